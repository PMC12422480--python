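"""Plurality-rule repertoire resolution and label-table rewriting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from callrep.confusion import ConfusionMatrix
from callrep.reference_data import (
    REFERENCE_LABELS,
    REFERENCE_MERGES,
    REFERENCE_RETAINED,
    REFERENCE_TOTAL_CALLS,
    reference_confusion,
)
from callrep.repertoire import (
    RepertoireMapping,
    apply_mapping,
    resolve_repertoire,
    summarize,
)


def _cm(labels, rows):
    return ConfusionMatrix(tuple(labels), np.array(rows, dtype=int))


def test_three_class_worked_example():
    # A confused into B in a plurality of cases; B and C perfectly classified
    cm = _cm("ABC", [[20, 50, 30], [0, 100, 0], [0, 0, 100]])
    m = resolve_repertoire(cm)
    assert m.target == {"A": "B", "B": "B", "C": "C"}
    assert m.retained == {"A": False, "B": True, "C": True}
    assert len(m.retained_labels) == 2


def test_identity_matrix_all_retained():
    cm = _cm("xyz", np.diag([5, 7, 9]))
    m = resolve_repertoire(cm)
    assert m.retained_labels == ["x", "y", "z"]
    assert all(m.target[l] == l for l in "xyz")


def test_reference_matrix_reproduces_published_merges():
    m = resolve_repertoire(reference_confusion())
    assert set(m.retained_labels) == set(REFERENCE_RETAINED)
    assert len(m.retained_labels) == 11
    for orig, tgt in REFERENCE_MERGES.items():
        assert not m.retained[orig]
        assert m.target[orig] == tgt
    for lab in REFERENCE_RETAINED:
        assert m.target[lab] == lab


def test_tie_for_row_maximum_is_retained_and_logged():
    cm = _cm("AB", [[5, 5], [0, 9]])
    m = resolve_repertoire(cm)
    assert m.retained["A"]
    assert any("tie" in n for n in m.notes)


def test_chain_resolves_to_retained_type():
    # A merges into B, but B itself merges into C
    cm = _cm("ABC", [[1, 5, 0], [0, 2, 5], [0, 0, 9]])
    m = resolve_repertoire(cm)
    assert m.target == {"A": "C", "B": "C", "C": "C"}
    assert any("chain" in n for n in m.notes)


def test_cycle_merges_into_largest_member():
    # A and B each confused mostly into the other; C independent
    cm = _cm("ABC", [[1, 5, 0], [7, 1, 0], [0, 0, 9]])
    m = resolve_repertoire(cm)
    assert any("cycle" in n for n in m.notes)
    # B has the larger row sum (8 > 6): cycle collapses onto B
    assert m.retained["B"] and not m.retained["A"]
    assert m.target["A"] == "B"


def test_exhaustive_small_matrices_always_resolve():
    """Every 3x3 count matrix with entries in {0,1,2} yields a valid,
    fully resolved mapping with at least one retained type."""
    labels = ("a", "b", "c")
    for cells in itertools.product(range(3), repeat=9):
        cm = ConfusionMatrix(labels, np.array(cells).reshape(3, 3))
        m = resolve_repertoire(cm)
        assert m.retained_labels, cells
        for l in labels:
            assert m.retained[m.target[l]], cells
            if m.retained[l]:
                assert m.target[l] == l


def test_mapping_validation_rejects_unresolved_targets():
    with pytest.raises(ValueError):
        RepertoireMapping(target={"a": "b", "b": "b"}, retained={"a": False, "b": False})


def test_mapping_json_roundtrip(tmp_path):
    m = resolve_repertoire(reference_confusion())
    p = tmp_path / "m.json"
    m.to_json(p)
    m2 = RepertoireMapping.from_json(p)
    assert m2.target == m.target and m2.retained == m.retained


def test_apply_mapping_identity_and_merge():
    table = pd.DataFrame(
        {
            "call_id": [f"c{i}" for i in range(6)],
            "original_label": ["A", "A", "B", "B", "C", "C"],
            "x": np.arange(6.0),
        }
    )
    ident = resolve_repertoire(_cm("ABC", np.diag([3, 3, 3])))
    assert apply_mapping(table, ident).equals(table)
    merged = resolve_repertoire(_cm("ABC", [[1, 4, 0], [0, 9, 0], [0, 0, 9]]))
    out = apply_mapping(table, merged)
    assert sorted(out["original_label"].unique()) == ["B", "C"]
    assert (out["x"] == table["x"]).all()
    assert out["original_label"].value_counts()["B"] == 4  # counts add up


def test_apply_mapping_unknown_label_raises():
    table = pd.DataFrame({"call_id": ["c"], "original_label": ["Z"], "x": [1.0]})
    m = resolve_repertoire(_cm("AB", np.diag([2, 2])))
    with pytest.raises(ValueError, match="Z"):
        apply_mapping(table, m)


def test_reference_mapping_applied_leaves_eleven_labels():
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "call_id": [f"c{i}" for i in range(150)],
            "original_label": rng.choice(REFERENCE_LABELS, 150),
            "x": rng.normal(size=150),
        }
    )
    out = apply_mapping(table, resolve_repertoire(reference_confusion()))
    assert out["original_label"].nunique() == 11


def test_summary_on_identity_matrix():
    s = summarize(_cm("ab", np.diag([10, 10])))
    assert s["agreement_pct"] == 100.0 and s["oob_error_pct"] == 0.0
    assert s["merges"] == {}


def test_summary_reference_headline_numbers():
    cm = reference_confusion()
    s = summarize(cm, n_total=REFERENCE_TOTAL_CALLS)
    assert s["trace"] == 842
    assert s["agreement_pct"] == 55.8
    assert s["oob_error_pct"] == 44.2
    assert s["chance_level_pct"] == 6.67
    assert s["binomial_p_value"] < 0.001
    assert s["n_retained"] == 11
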