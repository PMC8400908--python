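#!/usr/bin/env python
"""Univariate association tables on the margin-exact reconstructed cohort.

Rebuilds the 142-subject cohort whose per-column margins equal the
published counts, runs the univariate screen (grouped genotypes, H2/H2
indicator, clinical covariates) and writes a genotype-table-shaped TSV
(counts, percentages, test, p) plus crude ORs with Woolf intervals to
results/association.tsv.  The printed significant set — rs5050, rs4341,
rs4353, rs2640543, the H2/H2 diplotype and atrial fibrillation — should
reappear exactly.
"""

from pathlib import Path

import pandas as pd

from pgxbleed import published
from pgxbleed.association import univariate_screen
from pgxbleed.cohort_io import AnalysisTable, carrier_encode

OUT = Path(__file__).resolve().parents[1] / "results"

COVARIATES = [
    "sex_male", "age_ge_65", "hypertension", "diabetes_mellitus",
    "chronic_heart_failure", "atrial_fibrillation", "myocardial_infarction",
    "ace_inhibitor", "ace_h2h2",
]


def main() -> None:
    gm, pt = published.reconstruct_demo_cohort()
    cols = {s.snp_id: carrier_encode(gm, s.snp_id) for s in gm.snps}
    cols.update({c: pt.df[c].to_numpy(dtype=float) for c in COVARIATES})
    frame = pd.DataFrame(cols, index=pt.df.index)
    frame.insert(0, "bleeding", pt.bleeding)
    screen = univariate_screen(AnalysisTable(frame=frame))

    rows = []
    for name, res in screen.results.items():
        t = res.table
        rows.append({
            "variable": name,
            "exposed_cases": t.a, "exposed_controls": t.b,
            "unexposed_cases": t.c, "unexposed_controls": t.d,
            "pct_bleeding_exposed": round(100 * t.a / max(t.a + t.b, 1), 1),
            "or": round(res.or_point, 2),
            "ci_low": round(res.ci_low, 2), "ci_high": round(res.ci_high, 2),
            "p": round(res.p_value, 4), "method": res.method,
            "selected": name in screen.selected,
        })
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "association.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nselected for multivariable modelling: {screen.selected}")


if __name__ == "__main__":
    main()
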