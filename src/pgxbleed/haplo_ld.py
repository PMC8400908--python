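"""EM haplotype frequency estimation, linkage disequilibrium and diplotypes.

Population haplotype frequencies at a small block of biallelic loci are
estimated from unphased genotypes by expectation-maximization over phase
ambiguity: the E-step distributes each multilocus genotype's mass over all
phase-consistent ordered pairs in proportion to current pair probabilities
(2 f_i f_j off-diagonal, f_i^2 diagonal), the M-step re-estimates
frequencies from expected haplotype counts.  The observed-data
log-likelihood is non-decreasing across iterations, which the result
records and tests assert.

Genotypes are aggregated into distinct multilocus patterns before the EM
loop, so the per-iteration cost depends on the number of patterns (at most
3^k), not on cohort size.

Pairwise LD (|D'| and r^2) is computed from EM-estimated two-locus
haplotype frequencies; per-subject diplotypes are hard maximum-posterior
calls, with the posterior retained for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_io import GenotypeMatrix

__all__ = [
    "HaplotypeSet",
    "DiplotypeCall",
    "LDStats",
    "NoCompleteSubjectsError",
    "MonomorphicSnpError",
    "em_haplotype_frequencies",
    "filter_haplotypes",
    "assign_diplotypes",
    "hom_indicator",
    "pairwise_ld",
]


class NoCompleteSubjectsError(ValueError):
    """No subject has complete genotypes at the requested loci."""


class MonomorphicSnpError(ValueError):
    """LD is undefined when a locus is monomorphic."""


@dataclass
class HaplotypeSet:
    """Estimated haplotype frequencies at an ordered set of loci.

    ``haplotypes`` are allele strings (one base per locus, in locus order);
    ``freqs`` sum to one.  ``provenance`` holds the pre-filter frequencies
    after :func:`filter_haplotypes`.
    """

    loci: tuple
    haplotypes: tuple
    freqs: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    n_subjects: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.haplotypes) != len(self.freqs):
            raise ValueError("haplotypes/freqs length mismatch")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if any(len(h) != len(self.loci) for h in self.haplotypes):
            raise ValueError("haplotype string length must equal locus count")

    def freq_of(self, haplotype: str) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0

    def as_dict(self) -> dict:
        return dict(zip(self.haplotypes, map(float, self.freqs)))


@dataclass
class DiplotypeCall:
    """Hard maximum-posterior diplotype call for one subject."""

    subject_id: str
    best_pair: tuple | None
    posterior: float
    is_hom_for: str | None


@dataclass
class LDStats:
    """Pairwise linkage disequilibrium between two biallelic SNPs."""

    snp_a: str
    snp_b: str
    d_prime: float
    r2: float
    hap_freqs_2locus: dict

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.d_prime <= 1 + 1e-9 and -1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("|D'| and r^2 must lie in [0, 1]")


# ---------------------------------------------------------------------------
# internals


def _complete_patterns(gm: GenotypeMatrix, loci: Sequence[str]):
    """Distinct complete-case dosage patterns at the loci, with counts and
    the row index of each subject's pattern (-1 for incomplete subjects)."""
    idx = [gm.snp_index(l) for l in loci]
    sub = gm.dosage[:, idx]
    complete = (sub >= 0).all(axis=1)
    patterns, inverse = np.unique(sub[complete], axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(patterns))
    pattern_of = np.full(gm.n_subjects, -1, dtype=int)
    pattern_of[np.flatnonzero(complete)] = inverse
    return patterns, counts, pattern_of


def _haplotype_space(k: int) -> np.ndarray:
    """All 2^k haplotypes as minor-allele bit rows, in lexicographic order."""
    return np.array(
        [[(h >> (k - 1 - j)) & 1 for j in range(k)] for h in range(2**k)],
        dtype=np.int8,
    )


def _compatible_pairs(pattern: np.ndarray, hap_index: dict) -> list:
    """Unordered haplotype index pairs (i <= j) consistent with a dosage
    pattern: hets split one minor allele per haplotype, homs are fixed."""
    het = np.flatnonzero(pattern == 1)
    base = (pattern // 2).astype(np.int8)  # 1 only where dosage == 2
    if het.size == 0:
        i = hap_index[tuple(base)]
        return [(i, i)]
    pairs = []
    first, rest = het[0], het[1:]
    for mask in range(2 ** len(rest)):
        h1, h2 = base.copy(), base.copy()
        h1[first] = 1  # fix the first het to break pair symmetry
        for j, locus in enumerate(rest):
            if (mask >> j) & 1:
                h1[locus] = 1
            else:
                h2[locus] = 1
        pairs.append(tuple(sorted((hap_index[tuple(h1)], hap_index[tuple(h2)]))))
    return pairs


def _bits_to_string(bits: np.ndarray, gm: GenotypeMatrix, loci: Sequence[str]) -> str:
    out = []
    for j, locus in enumerate(loci):
        snp = gm.snp_def(locus)
        out.append(snp.minor_allele if bits[j] else snp.major_allele)
    return "".join(out)


# ---------------------------------------------------------------------------
# public operations


def em_haplotype_frequencies(gm: GenotypeMatrix, loci: Sequence[str],
                             tol: float = 1e-8,
                             max_iter: int = 1000) -> HaplotypeSet:
    """EM estimate of haplotype frequencies at ``loci`` (complete-case).

    Initialization is the product of observed allele frequencies (uniform
    over the haplotype space if a locus is monomorphic missing-wise), which
    is deterministic.  Convergence: max absolute frequency change < ``tol``.
    """
    loci = tuple(loci)
    k = len(loci)
    if k > 8:
        raise ValueError("haplotype block too long (complexity 2^k); k <= 8")
    patterns, counts, _ = _complete_patterns(gm, loci)
    if len(patterns) == 0:
        raise NoCompleteSubjectsError(
            f"no subject has complete genotypes at {loci}"
        )
    n = int(counts.sum())
    haps = _haplotype_space(k)
    hap_index = {tuple(row): i for i, row in enumerate(haps)}
    pair_lists = [_compatible_pairs(p, hap_index) for p in patterns]

    # init: product of observed minor-allele frequencies
    maf = (patterns * counts[:, None]).sum(axis=0) / (2.0 * n)
    freqs = np.prod(np.where(haps == 1, maf, 1.0 - maf), axis=1)
    if freqs.sum() <= 0:
        freqs = np.full(len(haps), 1.0 / len(haps))
    freqs = freqs / freqs.sum()

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros_like(freqs)
        loglik = 0.0
        for pairs, cnt in zip(pair_lists, counts):
            probs = np.array(
                [(1.0 if i == j else 2.0) * freqs[i] * freqs[j] for i, j in pairs]
            )
            total = probs.sum()
            if total <= 0:
                # pattern unexplained under current freqs; spread uniformly
                probs = np.full(len(pairs), 1.0 / len(pairs))
                total = 1.0
                loglik += cnt * -np.inf
            else:
                probs = probs / total
                loglik += cnt * np.log(total)
            for (i, j), w in zip(pairs, probs):
                expected[i] += cnt * w
                expected[j] += cnt * w
        trace.append(loglik)
        new_freqs = expected / (2.0 * n)
        delta = np.abs(new_freqs - freqs).max()
        freqs = new_freqs
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (last delta > {tol})",
            RuntimeWarning,
        )

    strings = tuple(_bits_to_string(row, gm, loci) for row in haps)
    return HaplotypeSet(
        loci=loci,
        haplotypes=strings,
        freqs=freqs,
        loglik_trace=np.array(trace),
        n_iter=it,
        converged=converged,
        n_subjects=n,
    )


def filter_haplotypes(hs: HaplotypeSet, min_freq: float) -> HaplotypeSet:
    """Drop haplotypes below ``min_freq`` and renormalize for reporting;
    the unfiltered frequencies are retained in ``provenance``."""
    keep = hs.freqs >= min_freq
    if not keep.any():
        raise ValueError(f"no haplotype reaches min_freq={min_freq}")
    freqs = hs.freqs[keep]
    return HaplotypeSet(
        loci=hs.loci,
        haplotypes=tuple(h for h, k in zip(hs.haplotypes, keep) if k),
        freqs=freqs / freqs.sum(),
        loglik_trace=hs.loglik_trace,
        n_iter=hs.n_iter,
        converged=hs.converged,
        n_subjects=hs.n_subjects,
        provenance={"unfiltered": hs.as_dict(), "min_freq": min_freq},
    )


def _pair_posteriors(pattern_haps: list, freq_of: dict):
    probs = np.array(
        [(1.0 if h1 == h2 else 2.0) * freq_of.get(h1, 0.0) * freq_of.get(h2, 0.0)
         for h1, h2 in pattern_haps]
    )
    total = probs.sum()
    return (probs / total, total) if total > 0 else (None, 0.0)


def assign_diplotypes(hs: HaplotypeSet, gm: GenotypeMatrix):
    """Hard maximum-posterior diplotype per subject.

    Ties are broken lexicographically on the (sorted) haplotype string
    pair.  Subjects whose genotype is incompatible with every retained
    haplotype are called against the unfiltered frequencies from
    ``provenance`` with a warning.  Subjects with a missing call at any
    locus get ``best_pair=None`` and posterior NaN.

    Returns the list of :class:`DiplotypeCall`.
    """
    loci = hs.loci
    k = len(loci)
    patterns, _, pattern_of = _complete_patterns(gm, loci)
    haps_bits = _haplotype_space(k)
    hap_index = {tuple(row): i for i, row in enumerate(haps_bits)}
    strings = [_bits_to_string(row, gm, loci) for row in haps_bits]

    freq_of = hs.as_dict()
    fallback = hs.provenance.get("unfiltered")
    pattern_calls = []
    used_fallback = False
    for pattern in patterns:
        pairs = _compatible_pairs(pattern, hap_index)
        named = [tuple(sorted((strings[i], strings[j]))) for i, j in pairs]
        post, total = _pair_posteriors(named, freq_of)
        if post is None and fallback:
            post, total = _pair_posteriors(named, fallback)
            used_fallback = used_fallback or post is not None
        if post is None:
            pattern_calls.append((None, np.nan))
            continue
        # maximum posterior; ties broken lexicographically on the pair
        top = post.max()
        maximal = [i for i in range(len(named)) if post[i] >= top - 1e-15]
        best = min(maximal, key=lambda i: named[i])
        pattern_calls.append((named[best], float(post[best])))
    if used_fallback:
        warnings.warn(
            "some genotypes are incompatible with the retained haplotypes; "
            "called against the unfiltered set", RuntimeWarning,
        )

    calls = []
    for i, subject in enumerate(gm.subjects):
        p = pattern_of[i]
        if p < 0:
            calls.append(DiplotypeCall(subject, None, float("nan"), None))
            continue
        pair, post = pattern_calls[p]
        hom = pair[0] if (pair is not None and pair[0] == pair[1]) else None
        calls.append(DiplotypeCall(subject, pair, post, hom))
    return calls


def hom_indicator(calls: Sequence[DiplotypeCall], haplotype: str) -> np.ndarray:
    """Binary vector: 1 where the best-pair call is homozygous for
    ``haplotype``, NaN where no call was possible."""
    out = np.empty(len(calls))
    for i, c in enumerate(calls):
        out[i] = np.nan if c.best_pair is None else float(c.is_hom_for == haplotype)
    return out


def pairwise_ld(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> LDStats:
    """|D'| and r^2 between two SNPs from EM two-locus haplotype
    frequencies.

    With minor-allele frequencies p_A, p_B and the estimated minor-minor
    haplotype frequency f_11: D = f_11 - p_A p_B; D' normalizes D by its
    admissible extreme given the allele frequencies; r^2 = D^2 /
    (p_A (1-p_A) p_B (1-p_B)).
    """
    hs = em_haplotype_frequencies(gm, (snp_a, snp_b))
    freqs = hs.freqs  # order: 00, 01, 10, 11 in minor-allele bits
    p_a = freqs[2] + freqs[3]
    p_b = freqs[1] + freqs[3]
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        raise MonomorphicSnpError(
            f"LD undefined: {snp_a} or {snp_b} is monomorphic"
        )
    d = freqs[3] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDStats(
        snp_a=snp_a,
        snp_b=snp_b,
        d_prime=float(min(d_prime, 1.0)),
        r2=float(min(r2, 1.0)),
        hap_freqs_2locus=hs.as_dict(),
    )
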