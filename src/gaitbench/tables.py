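"""Reconstruction oracle over the bundled published evaluation tables.

The package ships the per-class precision/recall/support values and the
aggregate metrics of a published clinical benchmark of this assessment
(five gait/posture items, LOOCV on 180 training participants and a
45-participant held-out test set).  Recomputing every aggregate from the
per-class values with :func:`gaitbench.metrics.reconstruct_from_table`
validates this package's metric conventions — in particular the handling
of classes that are never predicted (UNDEFINED precision/F1) — against
how the printed tables were actually aggregated.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .metrics import reconstruct_from_table

#: printed values carry 3 decimals; allow half an ulp of the printed
#: precision on either side after re-aggregation of rounded inputs
F1_TOL = 0.0015
ACC_TOL = 0.05  # percentage points, printed to 1 decimal


def load_reference_tables() -> dict:
    path = resources.files("gaitbench.data") / "reference_tables.json"
    return json.loads(path.read_text())


def verify_reference_tables(tables: dict | None = None) -> pd.DataFrame:
    """Recompute every reconstructible aggregate and compare to print.

    Returns one row per (item, split, metric) with the printed value, the
    value recomputed from per-class precision/recall/support, and a pass
    flag at the printed-precision tolerance.
    """
    tables = tables or load_reference_tables()
    rows = []
    for item, entry in tables["items"].items():
        for split in ("LOOCV", "TEST"):
            block = entry[split]
            rec = reconstruct_from_table(
                block["precision"], block["recall"], block["support"]
            )
            for metric, tol in (
                ("weighted_f1", F1_TOL),
                ("macro_f1", F1_TOL),
                ("acc_exact", ACC_TOL),
            ):
                printed = block[metric]
                computed = rec[metric]
                rows.append(
                    {
                        "item": item,
                        "split": split,
                        "metric": metric,
                        "printed": printed,
                        "computed": computed,
                        "abs_diff": abs(computed - printed),
                        "ok": abs(computed - printed) <= tol,
                    }
                )
            for c, (f1_printed, f1_computed) in enumerate(
                zip(block["f1"], rec["per_class_f1"])
            ):
                if f1_printed is None or f1_computed is None:
                    ok = f1_printed is None and f1_computed is None
                    diff = float("nan")
                else:
                    diff = abs(f1_computed - f1_printed)
                    ok = diff <= F1_TOL
                rows.append(
                    {
                        "item": item,
                        "split": split,
                        "metric": f"f1_class_{entry['classes'][c]}",
                        "printed": f1_printed,
                        "computed": f1_computed,
                        "abs_diff": diff,
                        "ok": ok,
                    }
                )
    return pd.DataFrame(rows)
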