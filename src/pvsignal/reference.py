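"""Bundled reference tables from a published retinal-vein-occlusion
pharmacovigilance study, used for analytic cross-checks and as the
default drug-class / synonym configuration.

The signal table carries the published per-drug statistics (ROR with
95% CI, PRR with chi-square, crude EBGM with EBGM05, IC with its printed
lower bound) for 25 signal-positive drugs; the onset table carries their
published median/Q1/Q3 onset days.  These values are *inputs* for
identity checks — e.g. that the published upper CI bound follows from
the estimate and lower bound by Wald log-symmetry — never outputs of
this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Published outcome-severity counts for the event cohort (denominator for
#: outcome percentages is the total number of outcome entries, 2789).
REFERENCE_OUTCOME_COUNTS = {
    "other_serious": 2062,
    "disability": 361,
    "hospitalization": 316,
    "death": 30,
    "life_threatening": 20,
}

#: Published sex split of the 2,304-case cohort.
REFERENCE_SEX_COUNTS = {"F": 1166, "M": 909, "unknown": 229}
REFERENCE_CASE_TOTAL = 2304

#: Published country mix (share of cases), used by the synthetic generator.
REFERENCE_COUNTRY_COUNTS = {
    "US": 793, "OTHER": 458, "JP": 335, "FR": 247, "GB": 170,
    "DE": 128, "CA": 73, "CN": 43, "IT": 33, "ES": 24,
}

#: The MedDRA Preferred Term code defining the target event.
TARGET_PT = "10038907"


def _read(name: str) -> pd.DataFrame:
    with resources.files("pvsignal.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def reference_signals() -> pd.DataFrame:
    """Published disproportionality statistics for the 25 signal drugs."""
    return _read("reference_signals.csv")


def reference_onsets() -> pd.DataFrame:
    """Published median/Q1/Q3 onset days per signal drug."""
    return _read("reference_onsets.csv")


def load_class_map() -> dict[str, tuple[str, str]]:
    """drug -> (ATC-level class label, drug-target class label)."""
    frame = _read("drug_classes.csv")
    return {
        r.drug: (r.atc_class, r.target_class) for r in frame.itertuples()
    }


def load_synonym_map() -> dict[str, str]:
    """Verbatim (brand or salt) name -> canonical generic name."""
    frame = _read("drug_synonyms.csv")
    return dict(zip(frame.verbatim, frame.canonical))
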