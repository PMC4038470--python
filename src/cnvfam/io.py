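"""Readers and writers for the on-disk formats.

Intensity channels are TSV matrices with probe rows and sample columns;
probe and region annotations are BED-like (0-based half-open); pedigrees
are PED-like (family, individual, father, mother, sex, phenotype) with a
TSV metadata sidecar keyed by sample id. Floats are written with 12
significant digits so write-then-read round-trips are lossless at that
precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AssociationResult, CohortTables, IntensityMatrix, Method

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"
RESULT_COLUMNS = (
    "cnv_id", "chrom", "start", "end", "component_index",
    "method", "statistic", "p_value", "n_transmissions",
)


def read_probe_annotation(path) -> pd.DataFrame:
    """BED-like probe annotation: chrom, start, end, probe_id, cnv_id[, probe_class]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 5:
        raise ValueError("probe annotation needs >=5 columns (chrom start end probe_id cnv_id)")
    cols = ["chrom", "start", "end", "probe_id", "cnv_id"]
    if df.shape[1] >= 6:
        cols.append("probe_class")
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if "probe_class" not in df.columns:
        df["probe_class"] = "internal_quantitative"
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r} in annotation")
    return df


def read_region_annotation(path) -> pd.DataFrame:
    """BED-like CNV regions: chrom, start, end, cnv_id[, cnv_type[, source_label]]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "cnv_id", "cnv_type", "source_label"][: df.shape[1]]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if df["cnv_id"].duplicated().any():
        raise ValueError("duplicate cnv_id in region annotation")
    return df


def write_region_annotation(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "cnv_id", "cnv_type", "source_label")
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_probe_annotation(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "probe_id", "cnv_id", "probe_class"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _read_channel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[df.dtypes == object]
    if len(bad):
        raise ValueError(f"non-numeric intensity values in column(s) {list(bad)}")
    if df.index.duplicated().any():
        raise ValueError("duplicate probe_id in intensity file")
    return df


def read_intensity(path_r, path_g, annotation_path) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Read paired channel TSVs (probe rows x sample columns) plus annotation.

    Probes are aligned to annotation order; probes absent from the
    annotation are dropped with a logged count. The two channels must list
    identical samples in identical order.
    """
    rdf = _read_channel(path_r)
    gdf = _read_channel(path_g)
    if list(rdf.columns) != list(gdf.columns):
        raise ValueError("channel sample order mismatch between R and G files")
    if list(rdf.index) != list(gdf.index):
        raise ValueError("probe order mismatch between R and G files")
    probes = read_probe_annotation(annotation_path)
    known = [p for p in probes["probe_id"] if p in rdf.index]
    n_dropped = rdf.shape[0] - len(known)
    if n_dropped:
        logger.warning("read_intensity: dropped %d probes absent from annotation",
                       n_dropped)
    probes = probes[probes["probe_id"].isin(set(rdf.index))].reset_index(drop=True)
    rdf = rdf.loc[known]
    gdf = gdf.loc[known]
    im = IntensityMatrix(
        sample_ids=list(rdf.columns),
        probe_ids=list(known),
        R=rdf.to_numpy(dtype=float).T,
        G=gdf.to_numpy(dtype=float).T,
    )
    return im, probes


def write_intensity(intensity: IntensityMatrix, path_r, path_g) -> None:
    for mat, path in ((intensity.R, path_r), (intensity.G, path_g)):
        pd.DataFrame(
            mat.T, index=pd.Index(intensity.probe_ids, name="probe_id"),
            columns=intensity.sample_ids,
        ).to_csv(path, sep="\t", float_format=FLOAT_FMT)


_SEX_FROM_PED = {1: "M", 2: "F"}
_SEX_TO_PED = {"M": 1, "F": 2, "unknown": 0}


def read_pedigree(ped_path, meta_path=None) -> CohortTables:
    """PED-like pedigree plus optional per-sample metadata TSV.

    PED columns: family, individual, father, mother, sex (1=M, 2=F,
    0=unknown), phenotype (2=affected). Metadata columns (keyed by
    sample_id): age_at_sampling (empty = missing, never 0), dna_source,
    plate_id, well_row, well_col. Children referencing an unknown parent id
    get that parent recorded as missing, with a warning. Families mixing DNA
    sources are marked source-inconsistent and excluded from association by
    default.
    """
    ped = pd.read_csv(
        ped_path, sep=r"\s+", header=None, dtype=str,
        names=["family_id", "sample_id", "father_id", "mother_id", "sex", "phenotype"],
    )
    ped = ped.set_index("sample_id")
    known = set(ped.index)
    for col in ("father_id", "mother_id"):
        missing_code = ped[col].isin({"0", "", "NA"}) | ped[col].isna()
        unknown = ~missing_code & ~ped[col].isin(known)
        if unknown.any():
            logger.warning("read_pedigree: %d %s reference unknown ids; recorded missing",
                           int(unknown.sum()), col)
        ped.loc[missing_code | unknown, col] = None
    samples = pd.DataFrame(index=ped.index)
    samples["family_id"] = ped["family_id"]
    samples["father_id"] = ped["father_id"]
    samples["mother_id"] = ped["mother_id"]
    samples["reported_sex"] = ped["sex"].astype(float).astype(int).map(
        _SEX_FROM_PED).fillna("unknown")
    samples["affected"] = ped["phenotype"].astype(float) == 2
    samples["age_at_sampling"] = np.nan
    samples["dna_source"] = "blood"
    for col in ("plate_id", "well_row", "well_col"):
        samples[col] = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        for col in ("age_at_sampling", "dna_source", "plate_id", "well_row", "well_col"):
            if col in meta.columns:
                samples[col] = meta[col].reindex(samples.index)
    cohort = CohortTables(samples=samples)
    n_bad = int((~cohort.samples["family_source_ok"]).sum())
    if n_bad:
        logger.warning("read_pedigree: %d samples in families mixing DNA sources "
                       "(excluded from association by default)", n_bad)
    return cohort


def write_pedigree(cohort: CohortTables, ped_path, meta_path) -> None:
    s = cohort.samples
    ped = pd.DataFrame({
        "family_id": s["family_id"],
        "sample_id": s.index,
        "father_id": s["father_id"].fillna("0"),
        "mother_id": s["mother_id"].fillna("0"),
        "sex": s["reported_sex"].map(_SEX_TO_PED).fillna(0).astype(int),
        "phenotype": np.where(s["affected"], 2, 1),
    })
    ped.to_csv(ped_path, sep="\t", header=False, index=False)
    meta = s[["age_at_sampling", "dna_source", "plate_id", "well_row", "well_col"]].copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t", float_format=FLOAT_FMT)


def write_results(results: list[AssociationResult], path, regions: pd.DataFrame | None = None) -> None:
    """Write association results as a TSV sorted by (chrom, start, cnv_id, component).

    ``regions`` maps cnv_id to coordinates; loci without coordinates sort
    last. Byte-deterministic for fixed input.
    """
    coords = {}
    if regions is not None:
        coords = {r["cnv_id"]: (r["chrom"], int(r["start"]), int(r["end"]))
                  for _, r in regions.iterrows()}
    rows = []
    for r in results:
        chrom, start, end = coords.get(r.cnv_id, ("", -1, -1))
        rows.append({
            "cnv_id": r.cnv_id, "chrom": chrom, "start": start, "end": end,
            "component_index": r.component_index,
            "method": r.method.value if isinstance(r.method, Method) else str(r.method),
            "statistic": r.statistic, "p_value": r.p_value,
            "n_transmissions": r.n_transmissions,
        })
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df = df.sort_values(
        ["chrom", "start", "cnv_id", "component_index"], kind="mergesort"
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path) -> list[AssociationResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(AssociationResult(
            cnv_id=str(r["cnv_id"]),
            statistic=float(r["statistic"]),
            p_value=float(r["p_value"]),
            n_transmissions=int(r["n_transmissions"]),
            method=Method(r["method"]),
            component_index=int(r["component_index"]),
        ))
    return out


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.index.name = "sample_id"
    scores.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
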