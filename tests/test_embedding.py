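import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import radskin as rs
from radskin.embedding import classical_mds, sammon_stress, uncentered_pearson_matrix
from radskin.errors import DataError


def dist_matrix(points):
    return squareform(pdist(np.asarray(points, dtype=float)))


# ---- uncentered Pearson distance ---------------------------------------------


def test_uncentered_pearson_examples():
    assert rs.uncentered_pearson_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)
    assert rs.uncentered_pearson_distance([1, 0], [0, 1]) == pytest.approx(1.0)
    assert rs.uncentered_pearson_distance([1, 2], [2, 1]) == pytest.approx(0.2)
    # anti-proportional vectors reach the upper end of [0, 2]
    assert rs.uncentered_pearson_distance([1, 2], [-1, -2]) == pytest.approx(2.0)


def test_uncentered_pearson_rejects_zero_vector():
    with pytest.raises(DataError):
        rs.uncentered_pearson_distance([0, 0], [1, 2])


def test_uncentered_pearson_matrix_agrees_with_pairwise():
    rng = np.random.default_rng(0)
    cols = rng.uniform(1, 5, size=(30, 4))
    mat = uncentered_pearson_matrix(cols)
    for i, j in itertools.combinations(range(4), 2):
        assert mat[i, j] == pytest.approx(
            rs.uncentered_pearson_distance(cols[:, i], cols[:, j])
        )


# ---- Sammon mapping ------------------------------------------------------------


def test_exactly_realizable_configuration_has_zero_stress():
    pts = [[0.0, 0.0], [1.0, 0.0], [0.25, 2.0], [-1.5, 0.5]]
    emb = rs.sammon_map(dist_matrix(pts))
    assert emb.stress < 1e-6
    assert np.isfinite(emb.coords).all()


def test_equilateral_triangle_recovered():
    d = np.ones((3, 3)) - np.eye(3)
    emb = rs.sammon_map(d)
    D = pdist(emb.coords)
    assert np.all(np.abs(D - D.mean()) < 1e-6)  # equilateral up to rigid motion


def test_stress_descends_from_mds_init():
    rng = np.random.default_rng(1)
    pts = rng.standard_normal((10, 5))  # 5-D points cannot embed exactly in 2-D
    d = dist_matrix(pts)
    init_stress = sammon_stress(d, classical_mds(d, 2))
    emb = rs.sammon_map(d)
    assert emb.stress <= init_stress
    assert emb.stress >= 0.0


def test_stress_invariant_under_rigid_motion():
    rng = np.random.default_rng(2)
    pts = rng.standard_normal((8, 4))
    d = dist_matrix(pts)
    emb = rs.sammon_map(d)
    theta = 1.1
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = emb.coords @ rot.T + np.array([3.0, -7.0])
    assert sammon_stress(d, moved) == pytest.approx(emb.stress, abs=1e-12)


def test_sammon_deterministic_and_validates_input():
    d = dist_matrix(np.random.default_rng(3).standard_normal((6, 3)))
    a = rs.sammon_map(d, seed=1)
    b = rs.sammon_map(d, seed=1)
    np.testing.assert_array_equal(a.coords, b.coords)
    with pytest.raises(DataError):
        rs.sammon_map(d[:, :-1])
    asym = d.copy()
    asym[0, 1] += 1.0
    with pytest.raises(DataError):
        rs.sammon_map(asym)


def test_zero_offdiagonal_distance_perturbed_with_warning():
    d = dist_matrix([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])  # coincident points
    with pytest.warns(UserWarning, match="perturbed"):
        emb = rs.sammon_map(d)
    assert np.isfinite(emb.coords).all()


# ---- hierarchical clustering ----------------------------------------------------


def brute_force_average_linkage(d):
    """Oracle: naive agglomeration with average linkage, smallest-index ties."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0] - 1e-12:
                best = (dist, a, b)
        dist, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), dist))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_four_point_linkage_matches_brute_force():
    rng = np.random.default_rng(4)
    d = dist_matrix(rng.standard_normal((4, 3)))
    link = rs.hier_cluster(d)
    oracle = brute_force_average_linkage(d)
    # same merge heights and same merged leaf sets, in order
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(link)

    def leaves(node):
        return sorted(
            [node.id] if node.is_leaf() else leaves(node.left) + leaves(node.right)
        )

    nodes = {}

    def collect(node):
        if not node.is_leaf():
            nodes[node.dist] = leaves(node)
            collect(node.left)
            collect(node.right)

    collect(tree)
    for members, height in oracle:
        assert height == pytest.approx(min(nodes, key=lambda h: abs(h - height)))
        assert members in nodes.values()


def test_identical_samples_merge_at_zero_height():
    d = np.zeros((3, 3))
    link = rs.hier_cluster(d)
    assert np.allclose(link[:, 2], 0.0)


def test_two_planted_groups_split_at_top():
    rng = np.random.default_rng(5)
    a = rng.standard_normal((5, 20)) * 0.1
    b = rng.standard_normal((5, 20)) * 0.1 + 10.0
    d = dist_matrix(np.vstack([a, b]))
    link = rs.hier_cluster(d)
    from scipy.cluster.hierarchy import fcluster

    labels = fcluster(link, t=2, criterion="maxclust")
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
    assert labels[0] != labels[5]


def test_newick_export_parses():
    d = dist_matrix(np.random.default_rng(6).standard_normal((4, 3)))
    nwk = rs.linkage_to_newick(rs.hier_cluster(d), ["s1", "s2", "s3", "s4"])
    assert nwk.endswith(";")
    assert all(f"s{i}" in nwk for i in range(1, 5))
    assert nwk.count("(") == nwk.count(")") == 3


def test_lethal_vs_sublethal_separation_on_simulation(small_experiment):
    """The ordination separates lethal from sublethal arms more than
    replicate scatter within groups (the headline ordination property)."""
    matrix, _ = small_experiment
    keep = [
        s
        for s in matrix.sample_ids
        if matrix.meta.loc[s, "dose_gy"] in (1.0, 20.0)
        and matrix.meta.loc[s, "timepoint"] in ("2h", "d4", "d7")
    ]
    sub = matrix.subset_samples(keep)
    d = rs.expression_distances(sub, top_n_variable=500)
    emb = rs.sammon_map(d)
    doses = sub.meta["dose_gy"].to_numpy()
    tps = sub.meta["timepoint"].to_numpy()
    coords = emb.coords
    between = []
    within = []
    for i, j in itertools.combinations(range(len(keep)), 2):
        dist = np.linalg.norm(coords[i] - coords[j])
        if doses[i] != doses[j]:
            between.append(dist)
        elif tps[i] == tps[j]:
            within.append(dist)
    assert np.mean(between) > np.mean(within)
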