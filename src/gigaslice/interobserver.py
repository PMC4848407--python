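"""Inter-observer agreement over independent term assignments.

Several observers independently assign one ontology term per object of
interest (cells, phenotypes, ...).  The assignments form an object x
category count table from which the module derives percent agreement,
Fleiss' kappa (the standard chance-corrected multi-rater statistic),
Cohen's kappa for the two-rater case, and the list of objects the
observers disagree on — the raw material for building a concordant ground
truth.

Fleiss' kappa over N objects, n raters and categories j:

    P_i  = [sum_j n_ij (n_ij - 1)] / [n (n - 1)]
    p_j  = sum_i n_ij / (N n)
    kappa = (mean_i P_i - sum_j p_j^2) / (1 - sum_j p_j^2)

Objects rated by a different number of observers than the majority are
excluded from kappa (reported separately), never imputed.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core_model import ValidationError


@dataclass
class AssignmentTable:
    objects: list                 # ordered object ids
    observers: list               # ordered observer ids
    categories: list              # ordered term ids
    counts: np.ndarray            # object x category assignment counts
    assignments: dict = field(default_factory=dict)  # (object, observer) -> term

    def raters_per_object(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_assignment_table(assignments) -> AssignmentTable:
    """Tabulate (object_id, observer_id, term_id) triples.

    Each observer may rate an object at most once; the table covers the
    union of rated objects, and an observer who skipped an object simply
    does not contribute to that row.
    """
    seen: dict = {}
    for obj, obs, term in assignments:
        if (obj, obs) in seen:
            raise ValidationError(f"observer {obs} rated object {obj} twice")
        seen[(obj, obs)] = term
    objects = sorted({o for o, _ in seen})
    observers = sorted({ob for _, ob in seen})
    categories = sorted(set(seen.values()))
    counts = np.zeros((len(objects), len(categories)), dtype=np.int64)
    obj_row = {o: i for i, o in enumerate(objects)}
    cat_col = {c: j for j, c in enumerate(categories)}
    for (obj, obs), term in seen.items():
        counts[obj_row[obj], cat_col[term]] += 1
    return AssignmentTable(objects=objects, observers=observers,
                           categories=categories, counts=counts,
                           assignments=seen)


def _eligible(table: AssignmentTable, min_raters=2):
    raters = table.raters_per_object()
    return np.flatnonzero(raters >= min_raters)


def percent_agreement(table: AssignmentTable) -> float:
    """Fraction of multiply-rated objects on which all raters agree."""
    rows = _eligible(table)
    if rows.size == 0:
        raise ValidationError("no object rated by >= 2 observers")
    counts = table.counts[rows]
    unanimous = (counts.max(axis=1) == counts.sum(axis=1)).sum()
    return float(unanimous / len(rows))


def fleiss_kappa(table: AssignmentTable) -> float:
    """Fleiss' kappa over objects sharing the modal rater count.

    Degenerate case: when all mass sits in one category, kappa is 1 for
    perfect agreement and undefined (error) otherwise.
    """
    raters = table.raters_per_object()
    rows = _eligible(table)
    if rows.size < 2:
        raise ValidationError("kappa needs >= 2 objects rated by >= 2 observers")
    n = int(Counter(raters[rows].tolist()).most_common(1)[0][0])
    rows = rows[raters[rows] == n]
    if rows.size < 2:
        raise ValidationError("fewer than 2 objects share the modal rater count")
    counts = table.counts[rows].astype(np.float64)
    N = counts.shape[0]
    P_i = (counts * (counts - 1)).sum(axis=1) / (n * (n - 1))
    P_bar = P_i.mean()
    p_j = counts.sum(axis=0) / (N * n)
    P_e = float((p_j ** 2).sum())
    if P_e == 1.0:
        if P_bar == 1.0:
            return 1.0
        raise ValidationError("kappa undefined: all ratings in one category")
    return float((P_bar - P_e) / (1.0 - P_e))


def cohen_kappa(table: AssignmentTable) -> float:
    """Two-rater chance-corrected agreement over the same table."""
    if len(table.observers) != 2:
        raise ValidationError("Cohen's kappa requires exactly 2 observers")
    a, b = table.observers
    pairs = [(table.assignments.get((o, a)), table.assignments.get((o, b)))
             for o in table.objects]
    pairs = [(x, y) for x, y in pairs if x is not None and y is not None]
    if not pairs:
        raise ValidationError("no object rated by both observers")
    cats = table.categories
    idx = {c: i for i, c in enumerate(cats)}
    M = np.zeros((len(cats), len(cats)))
    for x, y in pairs:
        M[idx[x], idx[y]] += 1
    M /= M.sum()
    po = np.trace(M)
    pe = float((M.sum(axis=1) * M.sum(axis=0)).sum())
    if pe == 1.0:
        if po == 1.0:
            return 1.0
        raise ValidationError("kappa undefined: all ratings in one category")
    return float((po - pe) / (1 - pe))


def list_disagreements(table: AssignmentTable) -> list:
    """Objects whose raters split across >= 2 categories, with each
    observer's choice; singleton-rater objects are excluded."""
    out = []
    for i, obj in enumerate(table.objects):
        row = table.counts[i]
        if row.sum() >= 2 and (row > 0).sum() >= 2:
            choices = {obs: table.assignments[(obj, obs)]
                       for obs in table.observers if (obj, obs) in table.assignments}
            out.append((obj, choices))
    return sorted(out, key=lambda item: item[0])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_assignments_csv(path) -> AssignmentTable:
    """Read ``object,observer,term`` rows into an assignment table."""
    with open(path, newline="") as fh:
        rows = [(r["object"], r["observer"], r["term"])
                for r in csv.DictReader(fh)]
    return build_assignment_table(rows)


def agreement_report(table: AssignmentTable, path=None) -> dict:
    """Summary JSON: sizes, percent agreement, kappa, disagreements."""
    report = {
        "n_objects": len(table.objects),
        "n_raters": len(table.observers),
        "n_categories": len(table.categories),
        "percent_agreement": percent_agreement(table),
        "kappa": fleiss_kappa(table),
        "disagreements": [
            {"object": obj, "choices": {str(k): v for k, v in choices.items()}}
            for obj, choices in list_disagreements(table)],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1)
    return report
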