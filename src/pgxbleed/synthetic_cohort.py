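"""Synthetic cohort generator with the study's statistical structure.

The generator emulates the population the analysis assumes: *ACE*
genotypes arise from two haplotypes drawn independently from the published
haplotype pool (Hardy-Weinberg at the haplotype level), every other SNP is
drawn under Hardy-Weinberg from its published minor-allele frequency,
binary covariates are independent Bernoulli draws at their published
prevalences, and the bleeding outcome follows a logistic model whose
default effect sizes are the published adjusted odds ratios.  The model
intercept is calibrated by exact enumeration so the expected marginal
incidence equals the target (21/142 by default).

What this deliberately does not emulate: covariate-covariate and
covariate-genotype correlation (none is estimable from the publication; a
hook accepts a user correlation matrix for covariates), LD between genes,
INR trajectories and time-to-event structure.  Follow-up time and INR are
decorative metadata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import published
from .cohort_io import GenotypeMatrix, PhenotypeTable, carrier_encode

__all__ = [
    "SimConfig",
    "calibrate_intercept",
    "expected_incidence",
    "expected_marginal_or",
    "simulate_cohort",
    "permute_outcome",
    "exposure_frame",
]


def exposure_frame(truth: dict) -> pd.DataFrame:
    """Model-term exposure vectors from a simulation truth record, as a
    design-ready DataFrame (one column per effect term)."""
    return pd.DataFrame({k: np.asarray(v) for k, v in truth["exposures"].items()})


def _default_betas() -> dict:
    return {term: math.log(aor) for term, aor in published.ADJUSTED_OR.items()}


def _default_mafs() -> dict:
    return {s.snp_id: s.maf for s in published.SNP_DEFS}


def _default_prevalences() -> dict:
    return dict(published.COVARIATE_PREVALENCES)


@dataclass
class SimConfig:
    """Generation parameters; defaults are the published study conditions.

    ``effect_betas`` maps term names to log-odds: ``<snp>_carrier`` terms
    resolve to the SNP's grouped-genotype exposure, ``ace_h2h2`` to the
    H2-homozygote diplotype indicator, anything else to a covariate column.
    ``covariate_corr`` optionally supplies a correlation matrix (order =
    sorted covariate names) for a Gaussian-copula draw of the binary
    covariates; the default is independence.
    """

    n_subjects: int = published.N_TOTAL
    ace_haplotypes: tuple = published.ACE_HAPLOTYPES
    snp_mafs: dict = field(default_factory=_default_mafs)
    covariate_prevalences: dict = field(default_factory=_default_prevalences)
    effect_betas: dict = field(default_factory=_default_betas)
    target_incidence: float = published.OVERALL_INCIDENCE
    missing_rate: float = 0.0
    seed: int = 0
    covariate_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        freqs = np.array([f for _, f in self.ace_haplotypes], dtype=float)
        if (freqs < 0).any() or freqs.sum() <= 0:
            raise ValueError("ACE haplotype frequencies must be nonnegative "
                             "with positive total mass")
        for sid, maf in self.snp_mafs.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"MAF for {sid} outside [0, 0.5]")
        if not 0.0 < self.target_incidence < 1.0:
            raise ValueError("target_incidence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def hap_sequences(self) -> list:
        return [h for h, _ in self.ace_haplotypes]

    @property
    def hap_freqs(self) -> np.ndarray:
        """Haplotype frequencies normalized to sum to one."""
        freqs = np.array([f for _, f in self.ace_haplotypes], dtype=float)
        return freqs / freqs.sum()

    def ace_allele_freq(self, snp_id: str) -> float:
        """Minor-allele frequency at an *ACE* locus implied by the pool."""
        pos = published.ACE_LOCI.index(snp_id)
        minor = published.SNP_BY_ID[snp_id].minor_allele
        return float(sum(f for (h, _), f in zip(self.ace_haplotypes, self.hap_freqs)
                         if h[pos] == minor))


# ---------------------------------------------------------------------------
# exposure probabilities and exact-enumeration calibration


def _exposure_probability(cfg: SimConfig, term: str) -> float:
    """Marginal exposure probability of a model term under the generator."""
    if term == "ace_h2h2":
        seqs = cfg.hap_sequences
        if published.H2_SEQUENCE not in seqs:
            return 0.0
        return float(cfg.hap_freqs[seqs.index(published.H2_SEQUENCE)] ** 2)
    if term.endswith("_carrier"):
        snp_id = term[: -len("_carrier")]
        snp = published.SNP_BY_ID[snp_id]
        if snp_id in published.ACE_LOCI:
            q = cfg.ace_allele_freq(snp_id)
        else:
            q = cfg.snp_mafs[snp_id]
        if snp.grouping == "carrier_dominant":
            return 1.0 - (1.0 - q) ** 2
        if snp.grouping == "variant_recessive":
            return 1.0 - q**2
        return 2.0 * q * (1.0 - q)
    if term in cfg.covariate_prevalences:
        return float(cfg.covariate_prevalences[term])
    raise KeyError(f"cannot resolve exposure probability for term {term!r}")


def expected_incidence(cfg: SimConfig, intercept: float) -> float:
    """Expected marginal outcome probability by exact enumeration over the
    discrete joint exposure distribution (terms independent by design)."""
    terms = list(cfg.effect_betas)
    probs = [_exposure_probability(cfg, t) for t in terms]
    betas = [cfg.effect_betas[t] for t in terms]
    total = 0.0
    for states in itertools.product((0, 1), repeat=len(terms)):
        p_state = 1.0
        eta = intercept
        for x, p, b in zip(states, probs, betas):
            p_state *= p if x else (1.0 - p)
            eta += b * x
        total += p_state * expit(eta)
    return total


def calibrate_intercept(cfg: SimConfig, tol: float = 1e-12) -> float:
    """Intercept such that the enumerated expected incidence equals
    ``cfg.target_incidence`` (to well below 1e-6); deterministic."""
    target = cfg.target_incidence

    def gap(b0: float) -> float:
        return expected_incidence(cfg, b0) - target

    lo, hi = logit(target) - 30.0, logit(target) + 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("target incidence unattainable under these effects")
    return float(brentq(gap, lo, hi, xtol=tol))


def expected_marginal_or(cfg: SimConfig, term: str) -> float:
    """Crude (marginal) odds ratio for one term implied by the generative
    model, by exhaustive summation over the other exposure strata."""
    intercept = calibrate_intercept(cfg)
    terms = list(cfg.effect_betas)
    if term not in terms:
        raise KeyError(f"{term!r} is not a model term")
    others = [t for t in terms if t != term]
    probs = {t: _exposure_probability(cfg, t) for t in terms}
    risk = {}
    for x_term in (0, 1):
        num = 0.0
        for states in itertools.product((0, 1), repeat=len(others)):
            p_state = 1.0
            eta = intercept + cfg.effect_betas[term] * x_term
            for t, x in zip(others, states):
                p_state *= probs[t] if x else (1.0 - probs[t])
                eta += cfg.effect_betas[t] * x
            num += p_state * expit(eta)
        risk[x_term] = num
    odds = {k: v / (1.0 - v) for k, v in risk.items()}
    return odds[1] / odds[0]


# ---------------------------------------------------------------------------
# simulation


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names = sorted(cfg.covariate_prevalences)
    n = cfg.n_subjects
    prev = np.array([cfg.covariate_prevalences[c] for c in names])
    if cfg.covariate_corr is None:
        draws = rng.random((n, len(names))) < prev
    else:
        corr = np.asarray(cfg.covariate_corr, dtype=float)
        if corr.shape != (len(names), len(names)):
            raise ValueError("covariate_corr shape must match the number of "
                             f"covariates ({len(names)}), in sorted-name order")
        z = rng.multivariate_normal(np.zeros(len(names)), corr, size=n,
                                    method="cholesky")
        from scipy.stats import norm

        draws = z < norm.ppf(prev)
    return pd.DataFrame(draws.astype(float), columns=names)


def simulate_cohort(cfg: SimConfig):
    """Draw one cohort; same config (including seed) gives identical output.

    Returns
    -------
    gm : GenotypeMatrix
    pt : PhenotypeTable
    truth : dict
        Latent state: haplotype pool and per-subject haplotype pair
        indices, the calibrated intercept, each model term's exposure
        vector, and the linear predictor.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    snps = list(published.SNP_DEFS)
    subjects = [f"P{i + 1:06d}" for i in range(n)]

    hap_freqs = cfg.hap_freqs
    seqs = cfg.hap_sequences
    hap_pairs = rng.choice(len(seqs), size=(n, 2), p=hap_freqs)
    # minor-allele indicator of each haplotype at each ACE locus
    hap_bits = np.array(
        [[int(seq[pos] == published.SNP_BY_ID[loc].minor_allele)
          for pos, loc in enumerate(published.ACE_LOCI)]
         for seq in seqs],
        dtype=np.int8,
    )

    dosage = np.empty((n, len(snps)), dtype=np.int8)
    for j, snp in enumerate(snps):
        if snp.snp_id in published.ACE_LOCI:
            pos = published.ACE_LOCI.index(snp.snp_id)
            dosage[:, j] = hap_bits[hap_pairs[:, 0], pos] + hap_bits[hap_pairs[:, 1], pos]
        else:
            dosage[:, j] = rng.binomial(2, cfg.snp_mafs[snp.snp_id], size=n)

    covars = _draw_covariates(cfg, rng)
    gm_full = GenotypeMatrix(subjects=subjects, snps=snps, dosage=dosage.copy())

    h2_idx = seqs.index(published.H2_SEQUENCE) if published.H2_SEQUENCE in seqs else -1
    exposures = {}
    for term in cfg.effect_betas:
        if term == "ace_h2h2":
            exposures[term] = (
                (hap_pairs[:, 0] == h2_idx) & (hap_pairs[:, 1] == h2_idx)
            ).astype(float)
        elif term.endswith("_carrier"):
            exposures[term] = carrier_encode(gm_full, term[: -len("_carrier")])
        else:
            exposures[term] = covars[term].to_numpy()

    intercept = calibrate_intercept(cfg)
    eta = np.full(n, intercept)
    for term, beta in cfg.effect_betas.items():
        eta += beta * exposures[term]
    y = rng.binomial(1, expit(eta)).astype(float)

    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = -1

    gm = GenotypeMatrix(subjects=subjects, snps=snps, dosage=dosage)

    df = covars.copy()
    df.index = pd.Index(subjects, name="subject_id")
    df.insert(0, "bleeding", y)
    # decorative metadata, consistent with the dichotomized age
    df["age_years"] = np.where(
        df["age_ge_65"] == 1, 65 + 15 * rng.random(n), 30 + 34.9 * rng.random(n)
    )
    df["inr_mean"] = np.clip(rng.normal(2.44, 0.10, size=n), 2.0, 3.0)
    df["followup_years"] = np.clip(rng.normal(14.3, 6.4, size=n), 0.5, None)
    df["valve_position"] = rng.choice(
        ["aortic", "mitral", "double", "tricuspid"], size=n,
        p=[0.24, 0.53, 0.17, 0.06],
    )
    pt = PhenotypeTable(df)

    truth = {
        "hap_sequences": list(seqs),
        "hap_freqs": hap_freqs.copy(),
        "hap_pairs": hap_pairs,
        "intercept": intercept,
        "effect_betas": dict(cfg.effect_betas),
        "exposures": exposures,
        "eta": eta,
    }
    return gm, pt, truth


def permute_outcome(pt: PhenotypeTable, seed: int) -> PhenotypeTable:
    """Uniformly permute the outcome labels; all other fields untouched."""
    rng = np.random.default_rng(seed)
    df = pt.df.copy()
    df["bleeding"] = rng.permutation(df["bleeding"].to_numpy())
    return PhenotypeTable(df)
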