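import numpy as np
import pandas as pd
import pytest

from cnvfam import CohortTables, LocusModel, SimConfig, simulate_cohort

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_trio_cohort(n_families: int, seed: int = 0, lcl_fraction: float = 0.0,
                     n_offspring: int = 1) -> CohortTables:
    """Lightweight pedigree of nuclear families (no intensities)."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        fam = f"F{f:05d}"
        src = "lcl" if rng.random() < lcl_fraction else "blood"
        fa, mo = f"{fam}_fa", f"{fam}_mo"
        for sid, sex, aff, age in (
            (fa, "M", False, float(rng.normal(40, 5))),
            (mo, "F", False, float(rng.normal(38, 5))),
        ):
            rows.append(dict(sample_id=sid, family_id=fam, father_id=None,
                             mother_id=None, reported_sex=sex, affected=aff,
                             age_at_sampling=age, dna_source=src,
                             plate_id="P1", well_row="A", well_col=1))
        for j in range(n_offspring):
            rows.append(dict(sample_id=f"{fam}_o{j}", family_id=fam,
                             father_id=fa, mother_id=mo,
                             reported_sex="M" if rng.random() < 0.5 else "F",
                             affected=True,
                             age_at_sampling=float(np.clip(rng.normal(12, 4), 1, 35)),
                             dna_source=src, plate_id="P1", well_row="A", well_col=1))
    return CohortTables(samples=pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def base_sim():
    """Shared small cohort: a null locus, a distorted locus, X controls."""
    loci = [
        LocusModel(cnv_id="NULL1", chrom="chr1", per_allele_or=1.0,
                   probe_slopes=0.5, noise_sd=0.08),
        LocusModel(cnv_id="RISK1", chrom="chr2", per_allele_or=2.0,
                   probe_slopes=0.5, noise_sd=0.08),
    ]
    cfg = SimConfig(n_families=150, loci=loci, n_x_control_regions=4, seed=11)
    return simulate_cohort(cfg)
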