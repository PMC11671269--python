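"""Ingest the synthetic quarter, join tables, deduplicate and filter.

Reports how many raw reports collapse to unique cases under the
keep-latest-receipt / highest-report-id rule, how many cases survive the
healthcare-professional filter, the size of the event cohort, and how
many drugs clear the three-event-case floor.  Writes
results/provenance.json and a per-case event CSV.
"""

import argparse
import glob
import json
import os

import pandas as pd

from pvsignal import faers_io, pipeline

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))


def load_quarter(quarter_dir: str):
    paths = sorted(
        p for p in glob.glob(os.path.join(quarter_dir, "*.txt"))
        if os.path.basename(p).upper()[:4] in faers_io.TABLE_NAMES
    )
    read = faers_io.read_quarter(paths)
    joined = faers_io.join_records(read.rows)
    return read, joined


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--quarters", default=os.path.join(ROOT, "scratch", "synth_quarter"))
    ap.add_argument("--results", default=os.path.join(ROOT, "results"))
    args = ap.parse_args()

    read, joined = load_quarter(args.quarters)
    config = pipeline.default_config()
    from pvsignal.preprocess import prepare_cases
    from pvsignal.reference import load_synonym_map

    case_set, eligible = prepare_cases(
        joined.records, config, load_synonym_map()
    )

    os.makedirs(args.results, exist_ok=True)
    provenance = {
        "malformed_rows": read.malformed_total,
        "orphan_child_rows": joined.orphans,
        **case_set.provenance,
    }
    with open(os.path.join(args.results, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2)
        fh.write("\n")

    event_rows = [
        {"caseid": c.caseid, "drug": d.name, "role": d.role,
         "reporter": c.reporter_occupation}
        for c in case_set.cases if c.caseid in case_set.event_caseids
        for d in c.drugs
    ]
    pd.DataFrame(event_rows).to_csv(
        os.path.join(args.results, "event_cases.csv"), index=False
    )

    print("stage counts:")
    for key, value in provenance.items():
        print(f"  {key}: {value}")
    print(f"eligible drugs (>= {config.min_reports_per_drug} event cases): "
          f"{len(eligible)}")
    print("  " + ", ".join(eligible[:10]) + (" ..." if len(eligible) > 10 else ""))


if __name__ == "__main__":
    main()
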