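"""Published aggregate inputs for the 2015 two-list analysis.

These are the printed aggregate quantities from the published 2015 study
of law-enforcement-related deaths (a news-media registry matched to vital
statistics): the two-list cell counts after redistribution of unmatched
cases, the list totals, the matching tallies the redistribution is based
on, and the exclusion-tally fixture.  ``reproduce_headline()`` recomputes
the headline estimates from these inputs alone.
"""

from __future__ import annotations

from . import capture

#: aggregate two-list cells after redistribution: media-only, vital-only, both
AGGREGATE_CELLS = {"n10": 599, "n01": 36, "n11": 487}

MEDIA_TOTAL = 1086  # included media-registry deaths
NVSS_TOTAL = 523  # public-use annual count of legal-intervention deaths
MATCHED_TOTAL = 991
MATCHED_CLASSIFIED = 444
UNMATCHED = 95

#: maximum plausible pairwise list correlation used for the sensitivity fit
MAX_LIST_CORRELATION = 0.93

#: raw-case exclusion tallies (media registry, 2015)
EXCLUSION_TALLY = {
    "total_reported": 1146,
    "vehicle_not_pursuit": 27,
    "domestic_violence": 6,
    "custody_no_mechanism": 23,
    "death_next_year": 3,
    "friendly_fire": 1,
}

#: matched/unmatched by death-investigator type (3 x 2)
INVESTIGATOR_MATCH_TABLE = [[582, 46], [380, 43], [29, 6]]

#: misclassified / properly classified by mechanism group
MECHANISM_MISCLASS = {"firearm": (486, 434), "non_firearm": (61, 10)}
TOTAL_MISCLASS = (547, 444)


def aggregate_cells_frame():
    import pandas as pd

    return pd.DataFrame([{"stratum": "2015", **AGGREGATE_CELLS}])


def reproduce_headline() -> dict:
    """Recompute the headline published estimates from the aggregate cells.

    Returns a dict with the independence fit (total, missing cell, CIs),
    per-list coverage, the redistribution split, and the dependence
    sensitivity fit at the maximum published list correlation.
    """
    cells = aggregate_cells_frame()
    independence = capture.fit_loglinear(cells, alpha=0.0)
    sensitivity = capture.fit_loglinear(cells, alpha=MAX_LIST_CORRELATION)
    coverage = capture.coverage_proportions(independence, MEDIA_TOTAL, NVSS_TOTAL)
    add_both, add_media = capture.redistribute_unmatched(
        UNMATCHED, MATCHED_CLASSIFIED, MATCHED_TOTAL
    )
    return {
        "cells": dict(AGGREGATE_CELLS),
        "n_hat": independence.n_hat,
        "n_hat_rounded": independence.n_hat_rounded,
        "n_hat_ci": [round(b) for b in independence.n_hat_ci],
        "n00_hat": independence.n00_hat,
        "n00_rounded": int(round(independence.n00_hat)),
        "n00_ci": [round(b) for b in independence.n00_ci],
        "coverage_nvss_pct": round(100 * coverage["nvss"].coverage, 1),
        "coverage_nvss_ci_pct": [round(100 * b, 1) for b in coverage["nvss"].ci],
        "coverage_media_pct": round(100 * coverage["media"].coverage, 1),
        "coverage_media_ci_pct": [round(100 * b, 1) for b in coverage["media"].ci],
        "redistribution": {"add_to_both": add_both, "add_to_media_only": add_media},
        "sensitivity_alpha": MAX_LIST_CORRELATION,
        "sensitivity_n_hat": sensitivity.n_hat,
        "sensitivity_n_hat_rounded": sensitivity.n_hat_rounded,
    }
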