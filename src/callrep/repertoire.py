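"""Resolving a putative repertoire with the confusion-matrix plurality rule.

A putative call type is kept as acoustically discriminable iff, in the
out-of-bag confusion matrix, a plurality of its calls were classified as
itself — i.e. the diagonal count is the strict maximum of its row.  A type
that fails the rule is relabelled wholesale to the type the classifier
confused it with most.  All merges are decided from the single input matrix;
there is no retraining after a merge.

Edge cases the published procedure never met are handled conservatively and
logged in the mapping's notes: a tie for the row maximum keeps the type; a
target that itself merged is followed transitively to a retained type; a
cycle among non-retained types collapses onto the cycle member with the
largest sample size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import chance_test
from .confusion import ConfusionMatrix

__all__ = ["RepertoireMapping", "resolve_repertoire", "apply_mapping", "summarize"]


@dataclass(frozen=True)
class RepertoireMapping:
    target: dict[str, str]  # original label -> final label
    retained: dict[str, bool]
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for orig, tgt in self.target.items():
            if not self.retained.get(tgt, False):
                raise ValueError(f"target {tgt!r} of {orig!r} is not a retained label")
        for lab, kept in self.retained.items():
            if kept and self.target[lab] != lab:
                raise ValueError(f"retained label {lab!r} must map to itself")

    @property
    def retained_labels(self) -> list[str]:
        return [l for l, kept in self.retained.items() if kept]

    @property
    def merged_labels(self) -> list[str]:
        return [l for l, kept in self.retained.items() if not kept]

    def to_dict(self) -> dict:
        return {
            l: {"target": self.target[l], "retained": self.retained[l]}
            for l in self.target
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mapping": self.to_dict(), "notes": list(self.notes)}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RepertoireMapping":
        obj = json.loads(Path(path).read_text())
        m = obj["mapping"]
        return cls(
            target={l: v["target"] for l, v in m.items()},
            retained={l: v["retained"] for l, v in m.items()},
            notes=tuple(obj.get("notes", [])),
        )


def resolve_repertoire(cm: ConfusionMatrix) -> RepertoireMapping:
    """Apply the plurality criterion to a confusion matrix."""
    labels = list(cm.labels)
    c = cm.counts
    notes: list[str] = []
    retained: dict[str, bool] = {}
    raw_target: dict[str, str] = {}

    for i, lab in enumerate(labels):
        row = c[i]
        rmax = row.max()
        argmaxes = np.where(row == rmax)[0]
        if row[i] == rmax:
            retained[lab] = True
            raw_target[lab] = lab
            if len(argmaxes) > 1:
                others = [labels[j] for j in argmaxes if j != i]
                notes.append(f"tie for row maximum in {lab!r} (with {others}); retained")
        elif len(argmaxes) > 1:
            # off-diagonal tie: deterministic lexicographic pick, logged
            pick = min(labels[j] for j in argmaxes)
            retained[lab] = False
            raw_target[lab] = pick
            notes.append(f"off-diagonal tie in {lab!r}; merged into {pick!r} (lexicographic)")
        else:
            retained[lab] = False
            raw_target[lab] = labels[int(argmaxes[0])]

    # resolve chains / cycles among non-retained labels
    target: dict[str, str] = {}
    row_sum = {lab: int(c[i].sum()) for i, lab in enumerate(labels)}
    for lab in labels:
        if retained[lab]:
            target[lab] = lab
            continue
        seen = [lab]
        cur = raw_target[lab]
        while not retained[cur] and cur not in seen:
            seen.append(cur)
            cur = raw_target[cur]
        if retained[cur]:
            if len(seen) > 1:
                notes.append(f"chain {' -> '.join(seen)} -> {cur} resolved to {cur!r}")
            target[lab] = cur
        else:
            # cycle: keep the member with the largest sample size
            cycle = seen[seen.index(cur):]
            keep = max(cycle, key=lambda l: (row_sum[l], l))
            notes.append(f"cycle {cycle} merged into {keep!r} (largest sample)")
            for m in cycle:
                retained[m] = m == keep
            target[lab] = keep

    # second pass: members of a broken cycle may already have targets recorded
    for lab in labels:
        cur = target[lab]
        while not retained[cur]:
            cur = target[cur]
        target[lab] = cur
        if retained[lab]:
            target[lab] = lab

    return RepertoireMapping(target=target, retained=retained, notes=tuple(notes))


def apply_mapping(table: pd.DataFrame, mapping: RepertoireMapping) -> pd.DataFrame:
    """Rewrite a feature table's labels to the resolved repertoire."""
    unknown = sorted(set(table["original_label"]) - set(mapping.target))
    if unknown:
        raise ValueError(f"labels not covered by the mapping: {unknown}")
    out = table.copy()
    out["original_label"] = out["original_label"].map(mapping.target)
    return out


def summarize(
    cm: ConfusionMatrix,
    mapping: RepertoireMapping | None = None,
    n_total: int | None = None,
) -> dict:
    """Headline numbers of a classification run.

    ``n_total`` overrides the matrix cell total when the dataset size is
    known independently (e.g. stated alongside a published table whose cells
    round to a slightly different sum).
    """
    if mapping is None:
        mapping = resolve_repertoire(cm)
    n = n_total if n_total is not None else cm.total
    agree = cm.trace / n
    test = chance_test(cm, n_total=n)
    return {
        "n_calls": n,
        "n_call_types": cm.k,
        "trace": cm.trace,
        "agreement_pct": round(100 * agree, 1),
        "oob_error_pct": round(100 * (1 - agree), 1),
        "chance_level_pct": round(100 / cm.k, 2),
        "binomial_p_value": test.p_value,
        "per_class_error": {l: round(float(e), 3) for l, e in cm.per_class_error().items()},
        "n_retained": len(mapping.retained_labels),
        "retained": mapping.retained_labels,
        "merges": {l: mapping.target[l] for l in mapping.merged_labels},
    }
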