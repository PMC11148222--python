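"""Screen every gene for differential HGG-vs-MET expression.

Computes ΔCt against TBP, then per gene a two-sided Mann-Whitney U test on
relative expression and the fold difference of cohort means; writes
results/screen.tsv and prints the significant genes.
"""

import argparse
from pathlib import Path

import glupanel as g
from glupanel.screen import write_screen


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    data = args.results_dir / "data"
    table = g.read_ct_table(data / "ct.csv")
    clinical = g.read_clinical_table(data / "clinical.csv")
    matrix = g.compute_delta_ct(g.collapse_replicates(table))
    g.write_expression_matrix(
        matrix,
        args.results_dir / "expression.tsv",
        args.results_dir / "expression_relative.tsv",
    )

    screen = g.screen_genes(matrix, clinical, alpha=args.alpha)
    write_screen(screen, args.results_dir / "screen.tsv")

    sig = screen[screen["significant"]].sort_values("p_value")
    print(f"{len(sig)}/{len(screen)} genes significant at p<{args.alpha}:")
    for _, row in sig.iterrows():
        print(f"  {row.gene:8s} fold {row.fold_difference:6.1f} ({row.direction}), "
              f"p={row.p_value:.2g}")
    print(f"wrote {args.results_dir/'screen.tsv'}")


if __name__ == "__main__":
    main()
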