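"""Preprocess the simulated cohorts, link ECGs to lab targets and split patients.

Reads the containers written by 01_simulate_cohorts.py, runs the trace
pipeline (resample to 128 Hz, high-pass, notch, pad to 1024 samples), the
±60-minute linking with median target assignment, the first-ECG rule for the
evaluation sets, and the 70/10/20 patient-level random/temporal split.
Writes a per-cohort linking/split summary and the splits map.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from ecglyte.io import read_cohort
from ecglyte.preprocessing import assemble_datasets


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--seed", type=int, default=2)
    args = ap.parse_args()
    out = Path(args.out_dir)

    rows = []
    for profile in ("strong", "weak", "null"):
        cohort = read_cohort(out / "cohorts" / profile)
        data = assemble_datasets(cohort, target_fs=128.0, target_len=1024,
                                 val_fraction_of_dev=0.15, seed=args.seed)
        (out / f"splits_{profile}.json").write_text(
            json.dumps(data["splits"].to_json_dict(), indent=1)
        )
        rows.append({
            "profile": profile,
            "ecgs_total": cohort.n_ecgs,
            "ecgs_unlinked": data["n_unlinked"],
            "post_cutoff_removed": data["splits"].n_removed_post_cutoff,
            **{k: len(data[k]) for k in ("train", "val", "random_test", "temporal_test")},
        })
        print(f"{profile}: {data['n_unlinked']} ECGs without an in-window lab; "
              f"train/val/random/temporal = "
              f"{len(data['train'])}/{len(data['val'])}/"
              f"{len(data['random_test'])}/{len(data['temporal_test'])}")

    pd.DataFrame(rows).to_csv(out / "linking_summary.csv", index=False)
    print(f"\nwrote {out / 'linking_summary.csv'}")


if __name__ == "__main__":
    main()
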