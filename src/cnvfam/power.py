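"""TDT power under a multiplicative disease model (Knapp-style).

For a biallelic locus with risk-allele frequency ``p`` and per-allele odds
ratio ``psi``, a heterozygous parent transmits the risk allele to an
affected offspring with probability tau = psi / (1 + psi). With ``n``
affected offspring each contributing two parental meioses, the expected
number of informative (heterozygous-parent) meioses is

    m = 2 n h,   h = P(parent heterozygous | offspring affected),

where h is computed exactly by enumerating the nine parental mating types
under Hardy-Weinberg, weighted by offspring affection probability
psi^(risk-allele count) (rare-disease scaling cancels). The transmission
count statistic is then approximately normal with noncentral mean
sqrt(m) * (2 tau - 1), giving the two-sided power at level alpha.

A mechanistic Monte-Carlo oracle (:func:`tdt_power_sim`) simulates
ascertained trios and runs the discrete TDT, cross-checking the analytic
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .simulate import sample_affected_trio_genotypes


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a TDT power calculation.

    ``n_offspring`` counts affected offspring; each contributes the two
    parental transmissions, matching the study's usage of "transmissions".
    """

    n_offspring: int
    risk_allele_freq: float
    per_allele_or: float
    alpha: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError("risk_allele_freq must lie in (0, 1)")
        if self.per_allele_or <= 0:
            raise ValueError("per_allele_or must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def transmission_prob(self) -> float:
        psi = self.per_allele_or
        return psi / (1.0 + psi)


def het_parent_prob_given_affected(p: float, psi: float) -> float:
    """P(a random parent is heterozygous | their offspring is affected)."""
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    trans = {0: (1.0, 0.0), 1: (0.5, 0.5), 2: (0.0, 1.0)}
    num = den = 0.0
    for gf in range(3):
        for gm in range(3):
            w = hwe[gf] * hwe[gm]
            aff = 0.0
            for af, pf in enumerate(trans[gf]):
                for am, pm in enumerate(trans[gm]):
                    aff += pf * pm * psi ** (af + am)
            den += w * aff
            num += w * aff * ((gf == 1) + (gm == 1)) / 2.0
    return num / den


def tdt_power(spec: PowerSpec) -> float:
    """Analytic normal-approximation power of the two-sided TDT."""
    h = het_parent_prob_given_affected(spec.risk_allele_freq, spec.per_allele_or)
    m = 2.0 * spec.n_offspring * h
    tau = spec.transmission_prob
    delta = np.sqrt(m) * (2.0 * tau - 1.0)
    z = stats.norm.isf(spec.alpha / 2.0)
    return float(stats.norm.sf(z - delta) + stats.norm.cdf(-z - delta))


def tdt_power_sim(
    spec: PowerSpec,
    n_reps: int = 10_000,
    seed: int = 0,
    chunk: int = 2_000_000,
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo TDT power with a 99% binomial (Wilson) confidence interval.

    Each replicate simulates ``spec.n_offspring`` ascertained affected trios
    mechanistically (Hardy-Weinberg parents, Mendelian transmission,
    multiplicative-penetrance rejection) and runs the discrete TDT
    Z = U / sqrt(V) with U the summed offspring-minus-midparent dosage and
    V = (number of heterozygous parents) / 4.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    n = spec.n_offspring
    rejections = 0
    # simulate in flat chunks of trios, then aggregate per replicate
    reps_per_chunk = max(1, chunk // n)
    done = 0
    while done < n_reps:
        r = min(reps_per_chunk, n_reps - done)
        gf, gm, gc = sample_affected_trio_genotypes(
            r * n, spec.risk_allele_freq, spec.per_allele_or, rng
        )
        gf = gf.reshape(r, n)
        gm = gm.reshape(r, n)
        gc = gc.reshape(r, n)
        U = (gc - (gf + gm) / 2.0).sum(axis=1)
        n_het = (gf == 1).sum(axis=1) + (gm == 1).sum(axis=1)
        V = n_het / 4.0
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = np.where(V > 0, U / np.sqrt(V), 0.0)
        rejections += int((np.abs(Z) > z_crit).sum())
        done += r
    phat = rejections / n_reps
    # Wilson 99% interval
    zq = stats.norm.isf(0.005)
    denom = 1.0 + zq**2 / n_reps
    center = (phat + zq**2 / (2 * n_reps)) / denom
    half = zq * np.sqrt(phat * (1 - phat) / n_reps + zq**2 / (4 * n_reps**2)) / denom
    return phat, (max(0.0, center - half), min(1.0, center + half))


def detectable_or(
    n_offspring: int,
    p: float,
    alpha: float,
    target_power: float,
    psi_max: float = 50.0,
) -> float:
    """Smallest per-allele odds ratio (> 1) reaching ``target_power``.

    Solved by root finding on the analytic power; accurate to 1e-6 in power.
    """
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")

    def f(psi: float) -> float:
        return tdt_power(PowerSpec(n_offspring, p, psi, alpha)) - target_power

    lo = 1.0 + 1e-12
    hi = 1.05
    while f(hi) < 0:
        hi *= 1.5
        if hi > psi_max:
            raise ValueError("target power unreachable below psi_max")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))
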