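"""Generate the synthetic study cohort used by the downstream analyses.

Emits a replicate-level Ct table (35 HGG + 20 MET samples, 29 glutamatergic
genes plus TBP, technical duplicates, 2% missing wells) and the matching
clinical table under results/data/.
"""

import argparse
from pathlib import Path

import glupanel as g


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = g.paper_default_config(seed=args.seed)
    table, clinical = g.generate_dataset(cfg)

    out = args.results_dir / "data"
    out.mkdir(parents=True, exist_ok=True)
    g.write_ct_table(table, out / "ct.csv")
    g.write_clinical_table(clinical, out / "clinical.csv")

    n_hgg = (clinical["cohort"] == "HGG").sum()
    n_met = (clinical["cohort"] == "MET").sum()
    n_missing = table.measurements["ct"].isna().sum()
    print(f"cohort: {n_hgg} HGG / {n_met} MET samples, "
          f"{len(table.genes) - 1} target genes + {table.housekeeping_gene}")
    print(f"{len(table.measurements)} Ct measurements "
          f"({n_missing} missing wells)")
    print(f"seizures in HGG: {int(clinical.loc[clinical.cohort=='HGG','seizures'].sum())}"
          f"/{n_hgg} (one undocumented)")
    print(f"wrote {out/'ct.csv'} and {out/'clinical.csv'}")


if __name__ == "__main__":
    main()
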