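"""Core data containers for the family-based CNV association workflow.

Coordinates are 0-based half-open (BED convention) everywhere. Intensity
matrices are oriented samples x probes; the two channels are the test (red,
``R``) and reference (green, ``G``) hybridization signals of a two-channel
comparative genomic hybridization array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PROBE_CLASSES = ("internal_quantitative", "breakpoint_qualitative")
CNV_TYPES = ("deletion", "duplication", "mixed", "multiallelic", "vntr", "control")
SEX_CODES = {1: "M", 2: "F", 0: "unknown"}


class Method(str, Enum):
    """Association-test variants."""

    FBAT_CNV = "fbat_cnv"
    FBAT_X = "fbat_x"
    LINEAR_TDT = "linear_tdt"
    CONDITIONAL_FBAT = "conditional_fbat"


@dataclass(frozen=True)
class ProbeAnnotation:
    """A single array probe mapped to a genomic interval and a CNV region."""

    probe_id: str
    chrom: str
    start: int
    end: int
    cnv_id: str
    probe_class: str = "internal_quantitative"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"probe {self.probe_id}: start must be < end")
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe_class {self.probe_class!r}")


@dataclass(frozen=True)
class CnvRegion:
    """A targeted copy-number-variable region."""

    cnv_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str = "deletion"
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.cnv_id}: start must be < end")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")


@dataclass
class IntensityMatrix:
    """Two-channel probe intensities for a set of samples.

    ``R`` and ``G`` hold nonnegative raw intensities of shape
    ``(n_samples, n_probes)``. ``normalized`` holds log2-ratio-scale values
    once a normalization scheme has been applied (NaN marks missing entries).
    """

    sample_ids: list[str]
    probe_ids: list[str]
    R: np.ndarray
    G: np.ndarray
    normalized: Optional[np.ndarray] = None
    norm_scheme: Optional[int] = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        shape = (len(self.sample_ids), len(self.probe_ids))
        if self.R.shape != shape or self.G.shape != shape:
            raise ValueError(
                f"channel shape {self.R.shape}/{self.G.shape} does not match "
                f"(n_samples, n_probes) = {shape}"
            )
        if np.nanmin(self.R, initial=0.0) < 0 or np.nanmin(self.G, initial=0.0) < 0:
            raise ValueError("raw channel intensities must be nonnegative")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != shape:
                raise ValueError("normalized matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def probe_indices(self, probe_ids: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        return np.array([lookup[p] for p in probe_ids], dtype=int)

    def normalized_frame(self) -> pd.DataFrame:
        if self.normalized is None:
            raise ValueError("matrix has not been normalized yet")
        return pd.DataFrame(
            self.normalized, index=self.sample_ids, columns=self.probe_ids
        )


@dataclass
class CohortTables:
    """Pedigree relations plus per-sample metadata.

    ``samples`` is indexed by sample_id with columns: family_id, father_id,
    mother_id, reported_sex (M/F/unknown), affected (bool), age_at_sampling
    (float years, NaN missing), dna_source (blood/lcl), plate_id, well_row,
    well_col, qc_pass (bool), family_source_ok (bool; families mixing DNA
    sources are excluded from association by default).
    """

    samples: pd.DataFrame

    REQUIRED = (
        "family_id",
        "father_id",
        "mother_id",
        "reported_sex",
        "affected",
        "age_at_sampling",
        "dna_source",
    )

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.samples.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        if "qc_pass" not in self.samples.columns:
            self.samples["qc_pass"] = True
        if "family_source_ok" not in self.samples.columns:
            src = self.samples.groupby("family_id")["dna_source"].nunique()
            ok = self.samples["family_id"].map(src.le(1))
            self.samples["family_source_ok"] = ok.to_numpy()

    def affected_trios(
        self, require_qc: bool = True, require_source_ok: bool = True
    ) -> pd.DataFrame:
        """One row per affected offspring with both parents in the cohort.

        Families lacking either parent are excluded (no imputation). Each
        returned row is one "transmission" in the sense used throughout:
        an affected offspring contributing two parental meioses. The result
        is cached per (require_qc, require_source_ok); mutate ``samples``
        only through a fresh :class:`CohortTables`.
        """
        key = (require_qc, require_source_ok)
        cache = self.__dict__.setdefault("_trio_cache", {})
        if key in cache:
            return cache[key]
        s = self.samples
        off = s[s["affected"].astype(bool)]
        if require_qc:
            off = off[off["qc_pass"].astype(bool)]
        if require_source_ok:
            off = off[off["family_source_ok"].astype(bool)]
        qc = s["qc_pass"].astype(bool) if require_qc else pd.Series(True, index=s.index)

        def parent_ok(ids: pd.Series) -> pd.Series:
            in_cohort = ids.notna() & ids.isin(s.index)
            passes = ids.map(qc)
            passes = passes.where(passes.notna(), False).astype(bool)
            return in_cohort & passes

        ok = parent_ok(off["father_id"]) & parent_ok(off["mother_id"])
        off = off[ok]
        out = pd.DataFrame({
            "family_id": off["family_id"].to_numpy(),
            "offspring": off.index.to_numpy(),
            "father": off["father_id"].to_numpy(),
            "mother": off["mother_id"].to_numpy(),
        }, columns=["family_id", "offspring", "father", "mother"])
        cache[key] = out
        return out

    def transmission_count(self, **kwargs) -> int:
        return len(self.affected_trios(**kwargs))


@dataclass(frozen=True)
class AssociationResult:
    """Per-locus association test outcome."""

    cnv_id: str
    statistic: float
    p_value: float
    n_transmissions: int
    method: Method
    component_index: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")
        if self.n_transmissions < 0:
            raise ValueError("n_transmissions must be >= 0")


@dataclass
class GenomewideSummary:
    """Genome-wide view of an association scan: QQ data, inflation, threshold."""

    overdispersion_slope: float
    bonferroni_threshold: float
    n_loci: int
    qq: pd.DataFrame = field(default_factory=pd.DataFrame)
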