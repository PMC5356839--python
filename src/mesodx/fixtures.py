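"""Packaged reference tables and consistency checks against them.

The package ships machine-readable transcriptions of the published panel
(codeset), the per-gene Mann-Whitney table, the two trained classifier
parameter sets, and the blind-set predictions.  ``verify_fixtures`` checks
that the statistical machinery reproduces the printed numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import CodeSet, default_codeset, _data_path
from .diffexp import count_significant, z_to_p, DEResult

Z_TO_P_TOL = 5e-6


@dataclass
class ReferenceFixtures:
    codeset: CodeSet
    de_table: pd.DataFrame       # gene, z, p, direction (117 rows)
    classifiers: dict            # classifier_1 / classifier_2 parameter sets
    blind_predictions: pd.DataFrame


def load_fixtures() -> ReferenceFixtures:
    with resources.as_file(_data_path("de_table.tsv")) as p:
        de = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path("usc_classifiers.json")) as p:
        classifiers = json.loads(p.read_text())
    with resources.as_file(_data_path("blind_predictions.tsv")) as p:
        blind = pd.read_csv(p, sep="\t")
    return ReferenceFixtures(
        codeset=default_codeset(),
        de_table=de,
        classifiers=classifiers,
        blind_predictions=blind,
    )


def de_table_results(fx: ReferenceFixtures | None = None) -> list[DEResult]:
    fx = fx or load_fixtures()
    return [DEResult(gene=r.gene, z=r.z, p=r.p, direction=r.direction)
            for r in fx.de_table.itertuples()]


def verify_fixtures(fx: ReferenceFixtures | None = None) -> dict:
    """Run every packaged-table consistency check; returns a report dict
    with an overall ``ok`` flag and per-check details."""
    fx = fx or load_fixtures()
    checks = []

    # (a) z -> p reproduces each printed p
    bad_rows = []
    for r in fx.de_table.itertuples():
        if abs(z_to_p(r.z) - r.p) > Z_TO_P_TOL:
            bad_rows.append({"gene": r.gene, "z": r.z, "printed_p": r.p,
                             "computed_p": z_to_p(r.z)})
    checks.append({
        "name": "z_to_p_agreement", "ok": not bad_rows,
        "tolerance": Z_TO_P_TOL, "n_rows": len(fx.de_table),
        "failures": bad_rows,
    })

    # (b) significance counts at both thresholds
    results = de_table_results(fx)
    got_05 = count_significant(results, 0.05)
    got_005 = count_significant(results, 0.005)
    checks.append({"name": "counts_alpha_0.05", "ok": got_05 == (35, 31),
                   "expected": (35, 31), "got": got_05})
    checks.append({"name": "counts_alpha_0.005", "ok": got_005 == (25, 18),
                   "expected": (25, 18), "got": got_005})

    # (c) total deregulated at 0.05
    total = int((fx.de_table.p < 0.05).sum())
    checks.append({"name": "total_significant_0.05", "ok": total == 66,
                   "expected": 66, "got": total})

    # (d) classifier gene-list lengths
    lens = tuple(len(fx.classifiers[k]["predictive_genes"])
                 for k in ("classifier_1", "classifier_2"))
    checks.append({"name": "classifier_sizes", "ok": lens == (22, 40),
                   "expected": (22, 40), "got": lens})

    # structural: panel composition
    cc = fx.codeset.class_counts()
    expected_cc = {"Endogenous": 117, "Housekeeping": 6,
                   "Positive": 6, "Negative": 8}
    checks.append({"name": "codeset_composition", "ok": cc == expected_cc,
                   "expected": expected_cc, "got": cc})
    checks.append({"name": "de_table_rows", "ok": len(fx.de_table) == 117,
                   "expected": 117, "got": len(fx.de_table)})

    return {"ok": all(c["ok"] for c in checks), "checks": checks}
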