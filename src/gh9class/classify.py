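"""Final class assignment from β″ intervals and the precision/recall report.

Each subclass owns one or more intervals on the ANN score β″; classes A
and C share one band that is split by a side condition on α₁₃ (small α₁₃
— classes A and C poorly separated from each other relative to B — votes
A, large α₁₃ votes C, and the boundary value matches neither).  Class B
carries a confidence split: B_high ("B+") for the lower, well-supported
interval and B_low ("B−") above it.  The rule table is data (YAML), so
intervals re-derived from a new reference run can be dropped in.

Evaluation tallies, per screening partition, matches (M) of the assigned
label (B_high/B_low collapsed to B) against the reference label inferred
from the maximum class-mean profile score, mismatches (MM) and
non-matches (NM, unassigned), with precision M/n and recall M/ΣM.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

LABELS = ("A", "B_high", "B_low", "C")
CONFIDENCE = {"B_high": "B+", "B_low": "B-"}


class RuleTableError(ValueError):
    pass


@dataclass(frozen=True)
class Rule:
    label: str
    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False
    alpha13_op: Optional[str] = None  # "lt" | "gt"
    alpha13_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise RuleTableError(f"bad label {self.label!r}")
        if self.lo > self.hi or (self.lo == self.hi and (self.lo_open or self.hi_open)):
            raise RuleTableError(f"empty interval in rule {self.label}: [{self.lo}, {self.hi}]")
        if (self.alpha13_op is None) != (self.alpha13_value is None):
            raise RuleTableError("alpha13 op and value must be set together")
        if self.alpha13_op not in (None, "lt", "gt"):
            raise RuleTableError(f"bad alpha13 op {self.alpha13_op!r}")

    def matches(self, beta_pp: float, alpha13: float) -> bool:
        if self.lo_open:
            if not beta_pp > self.lo:
                return False
        elif not beta_pp >= self.lo:
            return False
        if self.hi_open:
            if not beta_pp < self.hi:
                return False
        elif not beta_pp <= self.hi:
            return False
        if self.alpha13_op == "lt":
            return alpha13 < self.alpha13_value
        if self.alpha13_op == "gt":
            return alpha13 > self.alpha13_value
        return True


@dataclass
class RuleTable:
    rules: tuple

    def __post_init__(self) -> None:
        self.rules = tuple(self.rules)
        self.validate_disjoint()

    def validate_disjoint(self, n_grid: int = 2401,
                          alpha_grid: Sequence[float] = (0.0, 0.01, 0.02, 0.03)) -> None:
        """No two rules with different labels may match the same point.

        Checked on a dense β″ grid spanning the rule bounds (including every
        bound endpoint) crossed with representative α₁₃ values.
        """
        los = [r.lo for r in self.rules]
        his = [r.hi for r in self.rules]
        grid = np.unique(np.concatenate([
            np.linspace(min(los) - 1.0, max(his) + 1.0, n_grid), los, his]))
        for a13 in alpha_grid:
            for b in grid:
                hit = {r.label for r in self.rules if r.matches(float(b), a13)}
                if len(hit) > 1:
                    raise RuleTableError(
                        f"rules overlap at beta''={b:.6g}, alpha13={a13}: {sorted(hit)}")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RuleTable":
        rules = []
        for item in payload["rules"]:
            a13 = item.get("alpha13")
            rules.append(Rule(item["label"], float(item["lo"]), float(item["hi"]),
                              bool(item.get("lo_open", False)), bool(item.get("hi_open", False)),
                              None if a13 is None else a13["op"],
                              None if a13 is None else float(a13["value"])))
        return cls(tuple(rules))

    @classmethod
    def from_yaml(cls, path) -> "RuleTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "RuleTable":
        text = resources.files("gh9class").joinpath("data/rules.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        return {"rules": [
            {"label": r.label, "lo": r.lo, "hi": r.hi, "lo_open": r.lo_open,
             "hi_open": r.hi_open,
             "alpha13": None if r.alpha13_op is None else
             {"op": r.alpha13_op, "value": r.alpha13_value}}
            for r in self.rules]}


@dataclass
class ClassAssignment:
    seq_id: str
    beta_pp: float
    alpha13: float
    label: str  # A | B_high | B_low | C | unassigned
    confidence: Optional[str] = None  # B+ / B-
    well_spaced: Optional[bool] = None


def assign(seq_id: str, beta_pp: float, alpha13: float,
           rules: Optional[RuleTable] = None,
           well_spaced: Optional[bool] = None) -> ClassAssignment:
    """Assign the unique matching label, or ``unassigned``."""
    rules = rules or RuleTable.default()
    matched = [r.label for r in rules.rules if r.matches(beta_pp, alpha13)]
    label = matched[0] if matched else "unassigned"
    return ClassAssignment(seq_id, beta_pp, alpha13, label,
                           CONFIDENCE.get(label), well_spaced)


def assign_table(beta_pp: Mapping[str, float], alpha13: Mapping[str, float],
                 rules: Optional[RuleTable] = None,
                 well_spaced: Optional[Mapping[str, bool]] = None) -> pd.DataFrame:
    rules = rules or RuleTable.default()
    rows = []
    for sid in beta_pp:
        a = assign(sid, float(beta_pp[sid]), float(alpha13[sid]), rules,
                   None if well_spaced is None else well_spaced.get(sid))
        rows.append({"seq_id": a.seq_id, "beta_pp": a.beta_pp, "alpha13": a.alpha13,
                     "label": a.label, "confidence": a.confidence or "",
                     "well_spaced": a.well_spaced})
    return pd.DataFrame(rows).set_index("seq_id")


def collapse_b(label: str) -> str:
    return "B" if label in ("B_high", "B_low") else label


def evaluate(assignments: Mapping[str, str], reference: Mapping[str, str],
             partitions: Mapping[str, str],
             deltas: Optional[Mapping[str, Sequence[float]]] = None) -> pd.DataFrame:
    """Per-partition confusion counts and precision/recall.

    M counts sequences whose collapsed assignment (B_high/B_low → B)
    equals the reference label, MM disagreements, NM unassigned.
    Precision is M/n_seq within the partition; recall is M over the grand
    total of matches.  When per-sequence pairwise ΔHMM triples are given,
    their pooled median and mean per partition are reported alongside.
    """
    order = ("AA", "AB", "AC")
    total_m = 0
    rows = {}
    for part in order:
        ids = [i for i, p in partitions.items() if p == part]
        m = mm = nm = 0
        pooled = []
        for i in ids:
            lab = collapse_b(assignments.get(i, "unassigned"))
            if lab == "unassigned":
                nm += 1
            elif lab == collapse_b(reference[i]):
                m += 1
            else:
                mm += 1
            if deltas is not None and i in deltas:
                pooled.extend(float(x) for x in deltas[i])
        total_m += m
        rows[part] = {"n_seq": len(ids), "M": m, "MM": mm, "NM": nm,
                      "precision": m / len(ids) if ids else np.nan,
                      "delta_median": float(np.median(pooled)) if pooled else np.nan,
                      "delta_mean": float(np.mean(pooled)) if pooled else np.nan,
                      "n_obs": len(pooled)}
    for part in order:
        rows[part]["recall"] = rows[part]["M"] / total_m if total_m else np.nan
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "partition"
    return df[["n_seq", "M", "MM", "NM", "precision", "recall",
               "delta_median", "delta_mean", "n_obs"]]


def summarize_taxonomy(assignments: Mapping[str, str],
                       organisms: Mapping[str, str],
                       passing: Optional[Mapping[str, bool]] = None) -> pd.DataFrame:
    """Per-organism counts of A, B_high, B_low, C and screened totals."""
    rows = {}
    for sid, lab in assignments.items():
        org = organisms[sid]
        row = rows.setdefault(org, {"A": 0, "B_high": 0, "B_low": 0, "C": 0,
                                    "unassigned": 0, "total_passing": 0})
        row[lab if lab in row else "unassigned"] += 1
        if passing is None or passing.get(sid, False):
            row["total_passing"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "organism"
    return df


def derive_rule_bounds(beta_pp: Mapping[str, float], reference: Mapping[str, str],
                       mode: str = "minmax") -> RuleTable:
    """Re-derive per-class β″ intervals from a scored reference set.

    ``minmax`` takes the closed [min, max] interval of β″ per reference
    class, exactly the construction used to define intervals from a
    screened reference dataset.  ``midpoint`` then widens each interval to
    the midpoint of the gap to its neighbours (a Voronoi-style partition
    of the β″ axis), which is robust when within-class spread is tiny and
    a new sequence can land just outside the observed range.  The derived
    table carries no α₁₃ side conditions; class B maps to the B_high
    label.
    """
    if mode not in ("minmax", "midpoint"):
        raise ValueError(f"bad mode {mode!r}")
    by_class: dict = {}
    for sid, b in beta_pp.items():
        by_class.setdefault(collapse_b(reference[sid]), []).append(float(b))
    label_of = {"A": "A", "B": "B_high", "C": "C"}
    intervals = {c: (min(v), max(v)) for c, v in by_class.items()}
    if mode == "midpoint":
        ordered = sorted(intervals, key=lambda c: intervals[c][0])
        new = {}
        for k, c in enumerate(ordered):
            lo, hi = intervals[c]
            if k > 0:
                prev_hi = intervals[ordered[k - 1]][1]
                lo = (prev_hi + lo) / 2.0 if prev_hi < lo else lo
            else:
                lo = lo - (intervals[c][1] - intervals[c][0] + 1.0)
            if k < len(ordered) - 1:
                next_lo = intervals[ordered[k + 1]][0]
                hi = (hi + next_lo) / 2.0 if hi < next_lo else hi
            else:
                hi = hi + (intervals[c][1] - intervals[c][0] + 1.0)
            new[c] = (lo, hi)
        intervals = new
    rules = []
    for c, (lo, hi) in sorted(intervals.items()):
        rules.append(Rule(label_of.get(c, c), lo, hi,
                          lo_open=(mode == "midpoint"), hi_open=False))
    return RuleTable(tuple(rules))
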