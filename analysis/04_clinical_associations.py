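"""Seizure-association analyses within the HGG cohort.

Per-gene Mann-Whitney screen between seizure-positive and -negative HGG
patients plus point-biserial correlations of age and sex with seizure
occurrence; writes results/association.tsv.
"""

import argparse
from pathlib import Path

import glupanel as g
from glupanel.assoc import write_associations


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    data = args.results_dir / "data"
    table = g.read_ct_table(data / "ct.csv")
    clinical = g.read_clinical_table(data / "clinical.csv")
    matrix = g.compute_delta_ct(g.collapse_replicates(table))

    results = g.seizure_expression_screen(matrix, clinical, alpha=args.alpha)
    results.extend(g.clinical_seizure_associations(clinical))
    write_associations(results, args.results_dir / "association.tsv")

    genes = [r for r in results if r.kind == "mann_whitney" and r.defined]
    n_sig = sum(r.p_value < args.alpha for r in genes)
    best = min(genes, key=lambda r: r.p_value)
    print(f"seizure expression screen: {n_sig}/{len(genes)} genes with "
          f"p<{args.alpha} (smallest p: {best.variable}, p={best.p_value:.3f})")
    for r in results:
        if r.kind == "pearson":
            print(f"  {r.variable}: r={r.statistic:+.3f}, p={r.p_value:.3f} (n={r.n})")
    print(f"wrote {args.results_dir/'association.tsv'}")


if __name__ == "__main__":
    main()
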