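"""Six-pattern classification: standardization, rule cascade, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ionframe.experiments import PATTERN_ARCHETYPES
from ionframe.patterns import (
    Pattern,
    assign_pattern,
    assign_patterns,
    cluster_profiles,
    dendrogram_newick,
    exclude_non_metastatic,
    standardize_profiles,
)
from test_differential import make_matrix

TUMOR = ["nonmet", "primary", "kidney", "lung"]


def _z_table(rows):
    return pd.DataFrame(rows, columns=TUMOR, index=[f"P{i}" for i in range(len(rows))])


def test_standardize_hand_example():
    """Group means (1, 2, 3, 4) standardize to (-1.16, -0.39, 0.39, 1.16)."""
    x = np.repeat(np.array([[1.0, 2.0, 3.0, 4.0]]), 2, axis=0).reshape(1, -1)
    # build a matrix whose group means are 1..4 over the four tumor groups
    vals = np.array([[1, 1, 2, 2, 3, 3, 4, 4.0]])
    pm = make_matrix(vals, groups=TUMOR, n_rep=2)
    z = standardize_profiles(pm, TUMOR)
    np.testing.assert_allclose(
        z.iloc[0].to_numpy(), [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-5
    )


def test_standardize_constant_profile_warns_to_zero():
    pm = make_matrix(np.full((1, 8), 5.0), groups=TUMOR, n_rep=2)
    with pytest.warns(UserWarning, match="constant"):
        z = standardize_profiles(pm, TUMOR)
    assert (z.iloc[0] == 0).all()


def test_standardize_is_group_permutation_equivariant():
    vals = np.array([[1, 1, 5, 5, 2, 2, 8, 8.0]])
    pm = make_matrix(vals, groups=TUMOR, n_rep=2)
    z1 = standardize_profiles(pm, TUMOR)
    perm = ["kidney", "nonmet", "lung", "primary"]
    z2 = standardize_profiles(pm, perm)
    for g in TUMOR:
        assert z1.loc["P0", g] == pytest.approx(z2.loc["P0", g])


@pytest.mark.parametrize(
    "z,expected",
    [
        ((-1.5, 0.5, 0.5, 0.5), Pattern.METASTATIC),
        ((1.5, -0.5, -0.5, -0.5), Pattern.NON_METASTATIC),
        ((-0.5, 1.5, -0.5, -0.5), Pattern.PRIMARY_SITE),
        ((-0.8, -0.6, 0.7, 0.7), Pattern.KIDNEY_LUNG),
        ((-0.5, -0.5, 1.5, -0.5), Pattern.KIDNEY),
        ((-0.5, -0.5, -0.5, 1.5), Pattern.LUNG),
        ((-0.9, -0.3, 0.4, 0.8), Pattern.METASTATIC),  # cascade rule (b)
    ],
)
def test_assign_pattern_cases(z, expected):
    assert assign_pattern(np.array(z)) is expected


def _oracle_cascade(z, margin=0.5):
    """Independent re-coding of the rule table."""
    nm, p, k, l = z
    others = {"NM": [p, k, l], "P": [nm, k, l], "K": [nm, p, l], "L": [nm, p, k]}
    if nm - max(others["NM"]) >= margin:
        return Pattern.NON_METASTATIC
    if all(v - nm >= margin for v in (p, k, l)):
        return Pattern.METASTATIC
    if p - max(others["P"]) >= margin:
        return Pattern.PRIMARY_SITE
    if k - nm >= margin and l - nm >= margin and k - p >= margin and l - p >= margin:
        return Pattern.KIDNEY_LUNG
    if k - max(others["K"]) >= margin:
        return Pattern.KIDNEY
    if l - max(others["L"]) >= margin:
        return Pattern.LUNG
    order = [Pattern.NON_METASTATIC, Pattern.PRIMARY_SITE, Pattern.KIDNEY, Pattern.LUNG]
    return order[int(np.argmax(z))]


@given(st.lists(st.floats(min_value=-3, max_value=3), min_size=4, max_size=4))
@settings(max_examples=300, deadline=None)
def test_assignment_matches_rule_table_oracle(z):
    z = np.asarray(z)
    assert assign_pattern(z) is _oracle_cascade(z)


@given(
    st.lists(st.integers(min_value=-12, max_value=12), min_size=4, max_size=4),
    st.integers(min_value=-20, max_value=20),
)
@settings(max_examples=200, deadline=None)
def test_assignment_invariant_to_constant_shift(z, c):
    # quarter-steps are exact in binary, so the shifted comparisons are too
    z = np.asarray(z, dtype=float) * 0.25
    assert assign_pattern(z) is assign_pattern(z + c * 0.25)


def test_labels_partition_any_input():
    rng = np.random.default_rng(0)
    z = _z_table(rng.normal(0, 1, size=(94, 4)))
    out = assign_patterns(z)
    counts = out["pattern"].value_counts()
    assert counts.sum() == 94
    assert set(counts.index) <= {p.value for p in Pattern}


def test_archetype_accuracy_is_perfect():
    for label, z in PATTERN_ARCHETYPES.items():
        assert assign_pattern(np.array(z)) is label


def test_exclusion_arithmetic():
    """94 classified, 11 non-metastatic: 83 retained (set arithmetic)."""
    rows = [PATTERN_ARCHETYPES[Pattern.NON_METASTATIC]] * 11
    rows += [PATTERN_ARCHETYPES[Pattern.METASTATIC]] * 9
    rows += [PATTERN_ARCHETYPES[Pattern.PRIMARY_SITE]] * 6
    rows += [PATTERN_ARCHETYPES[Pattern.KIDNEY_LUNG]] * 31
    rows += [PATTERN_ARCHETYPES[Pattern.KIDNEY]] * 4
    rows += [PATTERN_ARCHETYPES[Pattern.LUNG]] * 33
    out = assign_patterns(_z_table(rows))
    assert len(out) == 94
    kept = exclude_non_metastatic(out)
    assert len(kept) == 83
    assert (out["excluded"].sum()) == 11
    # trivial edges
    assert len(exclude_non_metastatic(kept)) == 83
    all_nm = assign_patterns(_z_table([PATTERN_ARCHETYPES[Pattern.NON_METASTATIC]] * 3))
    assert len(exclude_non_metastatic(all_nm)) == 0


# --- clustering ------------------------------------------------------------


def test_identical_profiles_merge_first():
    z = _z_table([(1.0, 0.5, -0.5, -1.0), (1.0, 0.5, -0.5, -1.0), (-1.0, 1.0, 0.3, -0.3)])
    link, order, flat = cluster_profiles(z, n_clusters=2)
    assert link[0, 2] == pytest.approx(0.0, abs=1e-9)  # first merge at distance 0
    assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
    assert flat["P0"] == flat["P1"]


def test_anticorrelated_pair_merges_last():
    z = _z_table([(1.0, 0.5, -0.5, -1.0), (-1.0, -0.5, 0.5, 1.0), (0.5, -1.0, 1.0, -0.5)])
    link, _, _ = cluster_profiles(z)
    # final merge distance approaches 2 (1 - (-1))
    assert link[-1, 2] > 1.4
    from scipy.spatial.distance import correlation

    d01 = correlation(z.iloc[0], z.iloc[1])
    assert d01 == pytest.approx(2.0, abs=1e-9)


def _bruteforce_average_linkage(x, k):
    """Naive agglomerative average linkage on 1 - Pearson distances."""
    import itertools

    def dist(a, b):
        return float(np.mean([
            1 - np.corrcoef(x[i], x[j])[0, 1] for i in a for j in b
        ]))

    clusters = [frozenset([i]) for i in range(len(x))]
    while len(clusters) > k:
        best = min(itertools.combinations(clusters, 2), key=lambda ab: dist(*ab))
        clusters = [c for c in clusters if c not in best] + [best[0] | best[1]]
    return {i: ci for ci, c in enumerate(sorted(clusters, key=min)) for i in c}


def test_clustering_matches_bruteforce_on_small_input():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, size=(7, 4))
    z = _z_table(x)
    for k in (2, 3):
        _, _, flat = cluster_profiles(z, n_clusters=k)
        oracle = _bruteforce_average_linkage(x, k)
        # same partition up to label renaming
        ours = [flat.iloc[i] for i in range(7)]
        pairs_ours = {(i, j) for i in range(7) for j in range(i + 1, 7) if ours[i] == ours[j]}
        pairs_oracle = {
            (i, j) for i in range(7) for j in range(i + 1, 7) if oracle[i] == oracle[j]
        }
        assert pairs_ours == pairs_oracle


def test_clustering_membership_permutation_invariant():
    rng = np.random.default_rng(4)
    z = _z_table(rng.normal(size=(10, 4)))
    _, _, flat1 = cluster_profiles(z)
    perm = rng.permutation(10)
    z2 = z.iloc[perm]
    _, _, flat2 = cluster_profiles(z2)
    pairs1 = {(a, b) for a in z.index for b in z.index if a < b and flat1[a] == flat1[b]}
    pairs2 = {(a, b) for a in z.index for b in z.index if a < b and flat2[a] == flat2[b]}
    assert pairs1 == pairs2


def test_newick_roundtrip_parses():
    import io as _io

    from Bio import Phylo

    rng = np.random.default_rng(5)
    z = _z_table(rng.normal(size=(6, 4)))
    link, order, _ = cluster_profiles(z)
    nwk = dendrogram_newick(link, list(z.index))
    tree = Phylo.read(_io.StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(z.index)
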