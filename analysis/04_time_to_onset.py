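"""Time-to-onset analysis for the joint-signal drugs.

Summarizes days from therapy start to the event per drug and per ATC
class, fits Kaplan-Meier curves by class and runs the k-sample log-rank
test.  Writes results/onset_by_drug.csv, results/onset_by_class.csv and
results/km_curves.csv.
"""

import argparse
import importlib.util
import os

from pvsignal import grouping_report, pipeline

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--quarters", default=os.path.join(ROOT, "scratch", "synth_quarter"))
    ap.add_argument("--results", default=os.path.join(ROOT, "results"))
    args = ap.parse_args()

    spec = importlib.util.spec_from_file_location(
        "ingest", os.path.join(os.path.dirname(__file__), "02_ingest_and_dedup.py")
    )
    ingest = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(ingest)

    _, joined = ingest.load_quarter(args.quarters)
    result = pipeline.run_analysis(joined.records)

    os.makedirs(args.results, exist_ok=True)
    if result.onset_by_drug is None:
        print("no onset samples available")
        return
    result.onset_by_drug.to_csv(
        os.path.join(args.results, "onset_by_drug.csv"), index=False
    )
    result.onset_by_class.to_csv(
        os.path.join(args.results, "onset_by_class.csv"), index=False
    )
    grouping_report.km_table(result.km_curves).to_csv(
        os.path.join(args.results, "km_curves.csv"), index=False
    )

    c = result.onset_counters
    print(f"onset samples: {c.computed} computed, "
          f"{c.missing_date} excluded for missing/partial dates, "
          f"{c.negative} excluded as negative")
    print("median onset days by drug class:")
    for _, row in result.onset_by_class.iterrows():
        print(f"  {row['class']:<42} n={int(row['n']):<4} "
              f"median={row['median']:7.1f} "
              f"(Q1 {row['q1']:.1f}, Q3 {row['q3']:.1f})")
    if result.logrank:
        stat, p = result.logrank
        print(f"log-rank across classes: chi2={stat:.2f}, p={p:.2e}")


if __name__ == "__main__":
    main()
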