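"""Differential-table IO, BH adjustment, classification and set algebra."""

import numpy as np
import pandas as pd
import pytest

from codondep import omics_integration as oi
from codondep.synthetic_data import generate_planted_cohort


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value"])


# -------------------------------------------------------------------- IO ----

def test_read_toy_table(tmp_path):
    path = tmp_path / "prot.tsv"
    path.write_text(
        "gene_id\tlog2fc\tp_value\n"
        "g1\t-1.2\t0.01\n"
        "g2\t0.3\t0.5\n"
        "g3\t2.0\t0.001\n"
    )
    df = oi.read_differential_table(path, "protein")
    assert len(df) == 3
    assert df.loc[0, "log2fc"] == pytest.approx(-1.2)
    assert (df["layer"] == "protein").all()


def test_duplicate_gene_fatal(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("gene_id\tlog2fc\tp_value\ng1\t1\t0.1\ng1\t2\t0.2\n")
    with pytest.raises(oi.DuplicateGeneError, match="g1"):
        oi.read_differential_table(path, "protein")


def test_missing_columns_fatal(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("gene_id\tfc\n g1\t1\n")
    with pytest.raises(ValueError, match="missing required columns"):
        oi.read_differential_table(path, "protein")


def test_custom_column_map_and_nan_drop(tmp_path):
    path = tmp_path / "custom.tsv"
    path.write_text("Gene\tlogFC\tP.Value\ng1\t1.0\t0.1\ng2\tNA\t0.2\n")
    df = oi.read_differential_table(
        path, "mrna", columns={"gene": "Gene", "log2fc": "logFC", "p": "P.Value"}
    )
    assert list(df["gene_id"]) == ["g1"]


def test_round_trip_2000_rows(tmp_path, rng):
    n = 2000
    df = _table(
        {
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "log2fc": rng.normal(0, 1, n),
            "p_value": rng.uniform(0, 1, n),
        }
    )
    path = tmp_path / "rt.tsv"
    oi.write_differential_table(df, path)
    back = oi.read_differential_table(path, "protein")
    pd.testing.assert_frame_equal(back.drop(columns="layer"), df)


# ------------------------------------------------------------ adjustment ----

def test_bh_hand_example():
    df = _table({"gene_id": ["a", "b", "c"], "log2fc": [0, 0, 0],
                 "p_value": [0.01, 0.02, 0.03]})
    out = oi.adjust_pvalues(df, "bh")
    assert out["p_adjusted"].tolist() == pytest.approx([0.03, 0.03, 0.03])


def test_single_p_and_none_method():
    df = _table({"gene_id": ["a"], "log2fc": [0.0], "p_value": [0.2]})
    assert oi.adjust_pvalues(df, "bh")["p_adjusted"].item() == pytest.approx(0.2)
    assert oi.adjust_pvalues(df, "none")["p_adjusted"].item() == pytest.approx(0.2)


def test_bh_never_below_raw(rng):
    df = _table({"gene_id": [f"g{i}" for i in range(1000)],
                 "log2fc": np.zeros(1000), "p_value": rng.uniform(0, 1, 1000)})
    out = oi.adjust_pvalues(df)
    assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()


def test_bh_controls_null_discoveries(rng):
    """Uniform null p-values: BH at q=0.05 yields almost no discoveries."""
    hits = 0
    for _ in range(20):
        p = rng.uniform(0, 1, 1000)
        df = _table({"gene_id": [f"g{i}" for i in range(1000)],
                     "log2fc": np.zeros(1000), "p_value": p})
        hits += int((oi.adjust_pvalues(df)["p_adjusted"] < 0.05).sum())
    assert hits <= 0.05 * 20 * 1000 * 0.05  # far below the raw 5% rate


# ---------------------------------------------------------- classification ---

def test_definition_case_translational_down():
    protein = _table({"gene_id": ["g1"], "log2fc": [-1.2], "p_value": [0.01]})
    mrna = _table({"gene_id": ["g1"], "log2fc": [0.05], "p_value": [0.8]})
    res = oi.classify_translational_targets(protein, mrna, adjust="none")
    assert res["cls"].item() == "translational_down"


def test_unchanged_case():
    protein = _table({"gene_id": ["g1"], "log2fc": [0.1], "p_value": [0.6]})
    mrna = _table({"gene_id": ["g1"], "log2fc": [0.05], "p_value": [0.8]})
    res = oi.classify_translational_targets(protein, mrna)
    assert res["cls"].item() == "unchanged"


def test_planted_cohort_recovered_exactly():
    protein, mrna, truth = generate_planted_cohort(n_per_class=50, seed=7)
    res = oi.classify_translational_targets(protein, mrna, adjust="bh")
    merged = res.merge(truth, on="gene_id", suffixes=("", "_true"))
    assert (merged["cls"].astype(str) == merged["cls_true"]).all()
    counts = oi.class_counts(res)
    assert (counts == 50).all()


def test_classification_is_partition_and_order_invariant(rng):
    n = 400
    protein = _table({"gene_id": [f"g{i:03d}" for i in range(n)],
                      "log2fc": rng.normal(0, 1, n),
                      "p_value": rng.uniform(0, 1, n)})
    mrna = _table({"gene_id": [f"g{i:03d}" for i in range(n)],
                   "log2fc": rng.normal(0, 1, n),
                   "p_value": rng.uniform(0, 1, n)})
    res = oi.classify_translational_targets(protein, mrna)
    assert oi.class_counts(res).sum() == n  # partition: one class per gene
    shuffled = oi.classify_translational_targets(
        protein.sample(frac=1, random_state=1),
        mrna.sample(frac=1, random_state=2),
    )
    pd.testing.assert_frame_equal(res, shuffled)


def test_empty_join_fatal():
    protein = _table({"gene_id": ["a"], "log2fc": [1.0], "p_value": [0.1]})
    mrna = _table({"gene_id": ["b"], "log2fc": [1.0], "p_value": [0.1]})
    with pytest.raises(ValueError, match="no genes shared"):
        oi.classify_translational_targets(protein, mrna)


# ------------------------------------------------------------- set algebra ---

def test_intersection_examples():
    out = oi.intersect_signatures({"a", "b", "c"}, {"b", "c", "d"})
    assert out["intersection"] == {"b", "c"}
    assert out["sizes"] == (2, 1, 1)
    assert oi.intersect_signatures({"a"}, {"b"})["intersection"] == set()


def test_intersection_matches_oracle(rng):
    universe = [f"id{i}" for i in range(5000)]
    a = set(rng.choice(universe, 1000, replace=False))
    b = set(rng.choice(universe, 1000, replace=False))
    out = oi.intersect_signatures(a, b)
    inter = {x for x in universe if x in a and x in b}  # independent scan
    assert out["intersection"] == inter
    assert out["sizes"] == (len(inter), len(a) - len(inter), len(b) - len(inter))


def test_read_gene_set(tmp_path):
    path = tmp_path / "set.txt"
    path.write_text("g1\n\ng2\n g3 \n")
    assert oi.read_gene_set(path) == {"g1", "g2", "g3"}


# -------------------------------------------------------------- correlation ---

def test_correlation_perfect_and_anti():
    base = np.array([-1.0, 0.5, 2.0, -0.3])
    genes = [f"g{i}" for i in range(4)]
    prot = _table({"gene_id": genes, "log2fc": base, "p_value": [0.5] * 4})
    for sign, expected in ((1.0, 1.0), (-1.0, -1.0)):
        mrna = _table({"gene_id": genes, "log2fc": sign * base,
                       "p_value": [0.5] * 4})
        res = oi.classify_translational_targets(prot, mrna)
        assert oi.correlation_table(res)["pearson_r"] == pytest.approx(expected)


def test_correlation_undefined_below_three_genes():
    genes = ["g1", "g2"]
    prot = _table({"gene_id": genes, "log2fc": [1.0, -1.0], "p_value": [0.5, 0.5]})
    mrna = _table({"gene_id": genes, "log2fc": [0.5, 0.2], "p_value": [0.5, 0.5]})
    out = oi.correlation_table(oi.classify_translational_targets(prot, mrna))
    assert np.isnan(out["pearson_r"])
    assert out["class_counts"].sum() == 2


def test_planted_correlation_recovered(rng):
    """Bivariate normal with r=0.5, n=2000: estimate lands in [0.45, 0.55]."""
    n = 2000
    cov = [[1.0, 0.5], [0.5, 1.0]]
    xy = rng.multivariate_normal([0, 0], cov, n)
    genes = [f"g{i:04d}" for i in range(n)]
    prot = _table({"gene_id": genes, "log2fc": xy[:, 0],
                   "p_value": rng.uniform(0, 1, n)})
    mrna = _table({"gene_id": genes, "log2fc": xy[:, 1],
                   "p_value": rng.uniform(0, 1, n)})
    res = oi.classify_translational_targets(prot, mrna)
    assert 0.45 <= oi.correlation_table(res)["pearson_r"] <= 0.55
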