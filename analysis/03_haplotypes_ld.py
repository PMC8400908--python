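#!/usr/bin/env python
"""ACE haplotype estimation and within-gene LD on a synthetic cohort.

Runs the EM haplotype-frequency estimator on a 10,000-subject synthetic
cohort (haplotype structure is latent in the genotypes, so this exercises
phase reconstruction end to end), filters at the 1% reporting threshold,
computes all pairwise |D'| and r^2 in the ACE block, and summarizes
diplotype-call accuracy against the latent truth.  Outputs:
results/haplotypes.tsv and results/ld.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pgxbleed import published
from pgxbleed.haplo_ld import (
    assign_diplotypes,
    em_haplotype_frequencies,
    filter_haplotypes,
    pairwise_ld,
)
from pgxbleed.synthetic_cohort import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 7, n: int = 10_000) -> None:
    gm, _, truth = simulate_cohort(SimConfig(n_subjects=n, seed=seed))
    hs = em_haplotype_frequencies(gm, published.ACE_LOCI)
    kept = filter_haplotypes(hs, min_freq=0.01)
    gen = dict(zip(truth["hap_sequences"], truth["hap_freqs"]))
    hap_table = pd.DataFrame([
        {"haplotype": h, "em_freq": round(f, 4),
         "generating_freq": round(gen.get(h, 0.0), 4)}
        for h, f in sorted(kept.as_dict().items(), key=lambda kv: -kv[1])
    ])

    ld_rows = []
    loci = published.ACE_LOCI
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            ld = pairwise_ld(gm, loci[i], loci[j])
            ld_rows.append({"snp_a": loci[i], "snp_b": loci[j],
                            "d_prime": round(ld.d_prime, 3),
                            "r2": round(ld.r2, 3)})
    ld_table = pd.DataFrame(ld_rows)

    calls = assign_diplotypes(kept, gm)
    seqs = np.array(truth["hap_sequences"])
    accuracy = np.mean([
        tuple(sorted(seqs[p])) == c.best_pair
        for p, c in zip(truth["hap_pairs"], calls)
    ])

    OUT.mkdir(parents=True, exist_ok=True)
    hap_table.to_csv(OUT / "haplotypes.tsv", sep="\t", index=False)
    ld_table.to_csv(OUT / "ld.tsv", sep="\t", index=False)
    print(f"EM converged in {hs.n_iter} iterations (n={n}, seed {seed})")
    print(hap_table.to_string(index=False))
    print()
    print(ld_table.to_string(index=False))
    print(f"\nbest-pair diplotype calls matching latent truth: {accuracy:.3f}")


if __name__ == "__main__":
    main()
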