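"""Synthetic family cohorts with CNV genotypes and two-channel probe intensities.

The generator emulates the statistical structure of a family-based aCGH
study: nuclear families with one or two affected offspring, biallelic and
multi-allelic CNV/VNTR loci, a multiplicative per-allele disease odds ratio
psi driving transmission distortion, per-probe linear intensity response
with probe-specific informativeness and noise (including "unclusterable"
loci), DNA-source (blood vs immortalized cell line) and plate batch
effects, and age-dependent intensity trends at somatically rearranging
loci. The reference channel emulates a fixed pool of male genomic DNA:
autosomal reference copy number 2, chromosome X reference copy number 1,
which is what makes X-dosage sex inference possible downstream.

Disease model
-------------
Affection probability is proportional to psi^(number of risk alleles)
(multiplicative, rare-disease scaling cancels). Families are ascertained on
all offspring being affected, implemented by whole-family rejection
sampling; because loci act multiplicatively and independently, the
conditional genotype distribution factorizes across loci and each locus can
be rejected independently. A heterozygous parent then transmits the risk
allele to an affected offspring with probability psi / (1 + psi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CnvRegion, CohortTables, IntensityMatrix

logger = logging.getLogger(__name__)

BASELINE = 1000.0  # raw-intensity scale of a two-copy reference signal
ARRAY_EFFECT_SD = 0.10  # lognormal sigma of per-sample array (slide) effect
REFERENCE_NOISE_SD = 0.05  # lognormal sigma of reference-channel noise
PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


@dataclass(frozen=True)
class AgeEffect:
    """Age-dependent log2-ratio shift applied within one DNA source.

    ``kind`` is "none", "linear" (slope per year) or "spline"
    (interpolated through (age, shift) knots).
    """

    kind: str = "none"
    slope: float = 0.0
    knots: tuple[tuple[float, float], ...] = ()

    def shift(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, float)
        out = np.zeros_like(ages)
        ok = np.isfinite(ages)
        if self.kind == "linear":
            out[ok] = self.slope * ages[ok]
        elif self.kind == "spline":
            xs = np.array([k[0] for k in self.knots])
            ys = np.array([k[1] for k in self.knots])
            out[ok] = np.interp(ages[ok], xs, ys)
        elif self.kind != "none":
            raise ValueError(f"unknown age effect kind {self.kind!r}")
        return out


@dataclass(frozen=True)
class LocusModel:
    """Generative model for one CNV/VNTR locus.

    ``allele_copy_numbers`` gives the copy-number (or, for VNTRs, repeat
    length) contributed by each allele; a sample's probe signal is linear in
    the summed value of its two alleles. ``per_allele_or`` is the
    multiplicative disease odds ratio per copy of the risk allele
    (``risk_allele`` indexes into the allele list; 1.0 = null locus).
    Probe informativeness is controlled by slope/noise: clusterability
    roughly tracks min(beta_p) / sigma_p.
    """

    cnv_id: str
    chrom: str = "chr1"
    start: int = 1_000_000
    end: int = 1_010_000
    cnv_type: str = "deletion"
    allele_copy_numbers: tuple[float, ...] = (1.0, 2.0)
    allele_freqs: tuple[float, ...] = (0.4, 0.6)
    per_allele_or: float = 1.0
    risk_allele: int = 0
    n_probes: int = 4
    probe_slopes: tuple[float, ...] | float = 0.5
    noise_sd: tuple[float, ...] | float = 0.08
    age_effect: dict[str, AgeEffect] = field(default_factory=dict)
    source_shift: float = 0.0  # log2-ratio shift added for LCL samples
    has_tag_snp: bool = True  # emit a perfectly linked biallelic tag genotype

    def __post_init__(self) -> None:
        if abs(sum(self.allele_freqs) - 1.0) > 1e-9:
            raise ValueError(f"{self.cnv_id}: allele_freqs must sum to 1")
        if len(self.allele_freqs) != len(self.allele_copy_numbers):
            raise ValueError(f"{self.cnv_id}: allele list length mismatch")
        if self.per_allele_or <= 0:
            raise ValueError(f"{self.cnv_id}: per_allele_or must be > 0")

    def slopes(self) -> np.ndarray:
        b = np.broadcast_to(np.asarray(self.probe_slopes, float), (self.n_probes,))
        if (b <= 0).any():
            raise ValueError("probe slopes must be positive")
        return b.copy()

    def noise(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.noise_sd, float), (self.n_probes,)).copy()

    def region(self) -> CnvRegion:
        return CnvRegion(self.cnv_id, self.chrom, self.start, self.end,
                         cnv_type=self.cnv_type, source_label="simulated")


@dataclass
class SimConfig:
    """Cohort design. Defaults reproduce the study's family structure:

    2,160 nuclear families (76.9% with two affected offspring, the rest with
    one), a 15.5% cell-line-DNA family fraction, 96-well plates filled
    family-by-family, and founder genotypes in Hardy-Weinberg proportions.
    """

    n_families: int = 2160
    offspring_dist: dict[int, float] = field(
        default_factory=lambda: {2: 1661 / 2160, 1: 499 / 2160}
    )
    loci: list[LocusModel] = field(default_factory=list)
    fraction_lcl_families: float = 0.155
    n_x_control_regions: int = 0
    parent_age: tuple[float, float] = (40.0, 6.0)  # mean, sd (years)
    offspring_age: tuple[float, float] = (12.0, 5.0)
    seed: int = 0
    max_rejection_rounds: int = 100_000


@dataclass
class SimulatedCohort:
    """Everything a downstream stage may need, with ground truth attached."""

    intensity: IntensityMatrix
    cohort: CohortTables
    genotypes: pd.DataFrame  # sample x locus true summed copy number
    allele_counts: pd.DataFrame  # sample x locus count of risk allele (0/1/2)
    tag_genotypes: pd.DataFrame  # sample x tagged-locus tag-SNP dosage
    probes: pd.DataFrame
    regions: pd.DataFrame


# ---------------------------------------------------------------------------
# genotype-level machinery (shared with the power module's simulation oracle)
# ---------------------------------------------------------------------------

def sample_affected_trio_genotypes(
    n: int, p: float, psi: float, rng: np.random.Generator,
    max_rounds: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Risk-allele counts (father, mother, affected child) for n independent trios.

    Parents are drawn under Hardy-Weinberg at risk-allele frequency ``p``,
    the child by Mendelian transmission, and the whole trio accepted with
    probability psi^g / max(1, psi^2) — i.e. exact ascertainment on an
    affected child under the multiplicative model.
    """
    gf = np.empty(n, dtype=np.int64)
    gm = np.empty(n, dtype=np.int64)
    gc = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    norm = max(1.0, psi) ** 2
    rounds = 0
    while todo.size:
        m = todo.size
        f = rng.binomial(2, p, size=m)
        mo = rng.binomial(2, p, size=m)
        c = _transmit(f, rng) + _transmit(mo, rng)
        accept = rng.random(m) < (psi**c) / norm
        gf[todo[accept]] = f[accept]
        gm[todo[accept]] = mo[accept]
        gc[todo[accept]] = c[accept]
        todo = todo[~accept]
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError(
                "affected-trio rejection sampling failed to converge "
                f"(odds ratio {psi} too extreme; acceptance < 1e-6?)"
            )
    return gf, gm, gc


def _transmit(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted risk-allele count (0/1) per parent genotype 0/1/2."""
    u = rng.random(g.shape)
    return np.where(g == 2, 1, np.where(g == 1, (u < 0.5).astype(int), 0))


def _sample_family_alleles(
    locus: LocusModel,
    n_offspring: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int,
):
    """Allele-index pairs for founders and (ascertained) affected offspring.

    Returns (father_alleles (F,2), mother_alleles (F,2), offspring_alleles
    (F, max_k, 2) with -1 padding). Whole families are rejection-sampled so
    that every offspring is affected under the multiplicative model.
    """
    n_fam = len(n_offspring)
    K = len(locus.allele_freqs)
    max_k = int(n_offspring.max()) if n_fam else 0
    psi = locus.per_allele_or
    risk = locus.risk_allele
    freqs = np.asarray(locus.allele_freqs, float)

    fa = np.empty((n_fam, 2), dtype=np.int64)
    ma = np.empty((n_fam, 2), dtype=np.int64)
    oa = np.full((n_fam, max_k, 2), -1, dtype=np.int64)
    todo = np.arange(n_fam)
    norm_per_off = max(1.0, psi) ** 2
    rounds = 0
    while todo.size:
        m = todo.size
        f = rng.choice(K, size=(m, 2), p=freqs)
        mo = rng.choice(K, size=(m, 2), p=freqs)
        k_off = n_offspring[todo]
        off = np.full((m, max_k, 2), -1, dtype=np.int64)
        accept_p = np.ones(m)
        for j in range(max_k):
            active = k_off > j
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            a1 = f[np.arange(m), pick_f]
            a2 = mo[np.arange(m), pick_m]
            off[active, j, 0] = a1[active]
            off[active, j, 1] = a2[active]
            r = (a1 == risk).astype(int) + (a2 == risk).astype(int)
            accept_p = np.where(active, accept_p * psi**r / norm_per_off, accept_p)
        accept = rng.random(m) < accept_p
        fa[todo[accept]] = f[accept]
        ma[todo[accept]] = mo[accept]
        oa[todo[accept]] = off[accept]
        todo = todo[~accept]
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError(
                f"{locus.cnv_id}: family ascertainment acceptance too low "
                f"(odds ratio {psi})"
            )
    return fa, ma, oa


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _build_pedigree(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = sorted(config.offspring_dist)
    probs = np.array([config.offspring_dist[c] for c in counts], float)
    probs = probs / probs.sum()
    n_off = rng.choice(counts, size=config.n_families, p=probs)

    rows = []
    sid = 0
    plate, well = 0, 0
    for fam in range(config.n_families):
        fam_id = f"FAM{fam + 1:05d}"
        lcl = rng.random() < config.fraction_lcl_families
        source = "lcl" if lcl else "blood"
        members = [("father", "M", False), ("mother", "F", False)]
        members += [(f"off{j + 1}", "M" if rng.random() < 0.5 else "F", True)
                    for j in range(n_off[fam])]
        fam_sids = {}
        for role, sex, affected in members:
            sid += 1
            sample_id = f"S{sid:06d}"
            fam_sids[role] = sample_id
            if affected:
                mu, sd = config.offspring_age
                age = float(np.clip(rng.normal(mu, sd), 1.0, 35.0))
            else:
                mu, sd = config.parent_age
                age = float(np.clip(rng.normal(mu, sd), 22.0, 75.0))
            if well >= len(PLATE_ROWS) * PLATE_COLS:
                plate += 1
                well = 0
            rows.append({
                "sample_id": sample_id,
                "family_id": fam_id,
                "role": role,
                "father_id": None,
                "mother_id": None,
                "reported_sex": sex,
                "affected": affected,
                "age_at_sampling": age,
                "dna_source": source,
                "plate_id": f"P{plate + 1:03d}",
                "well_row": PLATE_ROWS[well // PLATE_COLS],
                "well_col": well % PLATE_COLS + 1,
            })
            well += 1
        for r in rows[-len(members):]:
            if r["role"].startswith("off"):
                r["father_id"] = fam_sids["father"]
                r["mother_id"] = fam_sids["mother"]
    df = pd.DataFrame(rows).drop(columns=["role"]).set_index("sample_id")
    return df


def _probe_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for locus in config.loci:
        span = max(locus.end - locus.start, locus.n_probes)
        for j in range(locus.n_probes):
            start = locus.start + (j * span) // locus.n_probes
            rows.append({
                "probe_id": f"{locus.cnv_id}_p{j + 1}",
                "chrom": locus.chrom,
                "start": start,
                "end": start + 60,
                "cnv_id": locus.cnv_id,
                "probe_class": "internal_quantitative",
            })
    return pd.DataFrame(rows)


def x_control_loci(n: int = 10) -> list[LocusModel]:
    """CNV-free chromosome-X control regions (copy number tracks sex)."""
    out = []
    for i in range(n):
        out.append(LocusModel(
            cnv_id=f"XCTRL{i + 1:02d}",
            chrom="chrX",
            start=10_000_000 + i * 1_000_000,
            end=10_005_000 + i * 1_000_000,
            cnv_type="control",
            allele_copy_numbers=(1.0,),
            allele_freqs=(1.0,),
            n_probes=3,
            probe_slopes=1.0,
            noise_sd=0.08,
            has_tag_snp=False,
        ))
    return out


def simulate_cohort(config: SimConfig, seed: Optional[int] = None) -> SimulatedCohort:
    """Generate intensities, pedigree tables and ground-truth genotypes.

    Deterministic given the seed (``seed`` overrides ``config.seed``). The
    test channel is R = BASELINE * array_effect * max(beta_p * dosage +
    noise, floor) * 2^(age/source shift); the reference channel is
    G = BASELINE * array_effect * ref_copy * lognormal noise with ref_copy
    2 on autosomes and 1 on chromosome X (male reference pool).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loci = list(config.loci)
    if config.n_x_control_regions:
        loci = loci + x_control_loci(config.n_x_control_regions)
    cfg = replace(config, loci=loci)

    samples = _build_pedigree(cfg, rng)
    sample_ids = list(samples.index)
    n_samples = len(sample_ids)
    is_off = samples["father_id"].notna().to_numpy()
    fam_ids = samples["family_id"].to_numpy()
    fam_list = list(dict.fromkeys(fam_ids))
    fam_index = {f: i for i, f in enumerate(fam_list)}
    n_off_per_fam = np.array([
        int(((fam_ids == f) & is_off).sum()) for f in fam_list
    ])
    # offspring slot within family, in sample order
    off_slot = np.full(n_samples, -1)
    counter: dict[str, int] = {}
    for i, (f, o) in enumerate(zip(fam_ids, is_off)):
        if o:
            off_slot[i] = counter.get(f, 0)
            counter[f] = off_slot[i] + 1
    father_row = {f: None for f in fam_list}
    mother_row = {f: None for f in fam_list}
    sex = samples["reported_sex"].to_numpy()
    for i, (f, o) in enumerate(zip(fam_ids, is_off)):
        if not o:
            (father_row if sex[i] == "M" else mother_row)[f] = i

    x_copies = np.where(sex == "F", 2.0, 1.0)
    ages = samples["age_at_sampling"].to_numpy()
    source = samples["dna_source"].to_numpy()

    probes = _probe_table(cfg)
    n_probes_total = len(probes)
    R = np.empty((n_samples, n_probes_total))
    G = np.empty((n_samples, n_probes_total))
    array_effect = np.exp(rng.normal(0.0, ARRAY_EFFECT_SD, size=n_samples))

    dosage_cols: dict[str, np.ndarray] = {}
    risk_cols: dict[str, np.ndarray] = {}
    tag_cols: dict[str, np.ndarray] = {}

    col0 = 0
    for locus in cfg.loci:
        cn = np.asarray(locus.allele_copy_numbers, float)
        if locus.chrom == "chrX" and locus.cnv_type == "control":
            dosage = x_copies.copy()
            risk = np.zeros(n_samples)
            ref_copy = 1.0
        else:
            fa, ma, oa = _sample_family_alleles(
                locus, n_off_per_fam, rng, cfg.max_rejection_rounds
            )
            pair = np.empty((n_samples, 2), dtype=np.int64)
            for i in range(n_samples):
                fi = fam_index[fam_ids[i]]
                if is_off[i]:
                    pair[i] = oa[fi, off_slot[i]]
                elif sex[i] == "M":
                    pair[i] = fa[fi]
                else:
                    pair[i] = ma[fi]
            dosage = cn[pair[:, 0]] + cn[pair[:, 1]]
            risk = ((pair[:, 0] == locus.risk_allele).astype(float)
                    + (pair[:, 1] == locus.risk_allele))
            ref_copy = 1.0 if locus.chrom == "chrX" else 2.0
            if locus.has_tag_snp:
                tag_cols[locus.cnv_id] = risk.copy()
        dosage_cols[locus.cnv_id] = dosage
        risk_cols[locus.cnv_id] = risk

        beta = locus.slopes()
        sigma = locus.noise()
        shift = np.zeros(n_samples)
        for src, eff in locus.age_effect.items():
            m = source == src
            shift[m] += eff.shift(ages[m])
        if locus.source_shift:
            shift[source == "lcl"] += locus.source_shift

        k = locus.n_probes
        sl = slice(col0, col0 + k)
        signal = beta[None, :] * dosage[:, None] + rng.normal(
            0.0, 1.0, size=(n_samples, k)
        ) * sigma[None, :]
        signal = np.maximum(signal, 0.01)
        R[:, sl] = (BASELINE * array_effect[:, None] * signal
                    * np.power(2.0, shift[:, None]))
        G[:, sl] = (BASELINE * array_effect[:, None] * ref_copy
                    * np.exp(rng.normal(0.0, REFERENCE_NOISE_SD, size=(n_samples, k))))
        col0 += k

    intensity = IntensityMatrix(
        sample_ids=sample_ids,
        probe_ids=list(probes["probe_id"]),
        R=R,
        G=G,
    )
    cohort = CohortTables(samples=samples)
    regions = pd.DataFrame([{
        "cnv_id": l.cnv_id, "chrom": l.chrom, "start": l.start,
        "end": l.end, "cnv_type": l.cnv_type, "source_label": "simulated",
    } for l in cfg.loci])
    return SimulatedCohort(
        intensity=intensity,
        cohort=cohort,
        genotypes=pd.DataFrame(dosage_cols, index=sample_ids),
        allele_counts=pd.DataFrame(risk_cols, index=sample_ids),
        tag_genotypes=pd.DataFrame(tag_cols, index=sample_ids),
        probes=probes,
        regions=regions,
    )


def inject_artifacts(
    intensity: IntensityMatrix,
    cohort: CohortTables,
    probes: pd.DataFrame,
    cnv_id: str,
    age_effect: Optional[dict[str, AgeEffect]] = None,
    source_shift: float = 0.0,
) -> IntensityMatrix:
    """Add age/source log2-ratio shifts to one locus's probes, in place.

    Shifts delta are applied multiplicatively to the test channel as
    2**delta, i.e. exactly delta on the log2-ratio scale; a null
    specification leaves the matrix bit-for-bit unchanged.
    """
    mask = probes["cnv_id"] == cnv_id
    if not mask.any():
        raise ValueError(f"unknown locus {cnv_id}")
    cols = intensity.probe_indices(list(probes.loc[mask, "probe_id"]))
    ages = cohort.samples["age_at_sampling"].reindex(intensity.sample_ids).to_numpy()
    source = cohort.samples["dna_source"].reindex(intensity.sample_ids).to_numpy()
    shift = np.zeros(len(intensity.sample_ids))
    for src, eff in (age_effect or {}).items():
        m = source == src
        shift[m] += eff.shift(ages[m])
    if source_shift:
        shift[source == "lcl"] += source_shift
    if np.any(shift != 0.0):
        intensity.R[:, cols] *= np.power(2.0, shift[:, None])
    return intensity
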