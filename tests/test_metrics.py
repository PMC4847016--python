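import math

import numpy as np
import pytest

from minescape import constants as C
from minescape.metrics import (
    MetricsReport,
    compute_metrics,
    connectance,
    contagion,
    contiguity_am,
    delineate_patches,
    enn_mn,
    landscape_shape_index,
    mean_patch_size,
    patch_size_cv,
    shdi,
    shei,
)
from minescape.raster import LandUseGrid


# ------------------------------------------------------------- oracles

def _flood_fill_patches(data, connectivity=8):
    """Independent patch delineation by explicit flood fill."""
    rows, cols = data.shape
    seen = np.zeros_like(data, dtype=bool)
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    patches = []
    for r in range(rows):
        for c in range(cols):
            if seen[r, c] or data[r, c] == -9999:
                continue
            code = data[r, c]
            stack, cells = [(r, c)], []
            seen[r, c] = True
            while stack:
                y, x = stack.pop()
                cells.append((y, x))
                for dy, dx in neigh:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < rows and 0 <= nx < cols and not seen[ny, nx] \
                            and data[ny, nx] == code:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            patches.append((code, cells))
    return patches


def _cell_adjacencies(data):
    """Double-counted 4-neighbour adjacency counts between valid cells."""
    rows, cols = data.shape
    g = {}
    for r in range(rows):
        for c in range(cols):
            if data[r, c] == -9999:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                nr, nc = r + dr, c + dc
                if nr < rows and nc < cols and data[nr, nc] != -9999:
                    a, b = int(data[r, c]), int(data[nr, nc])
                    g[(a, b)] = g.get((a, b), 0) + 1
                    g[(b, a)] = g.get((b, a), 0) + 1
    return g


def _oracle_contagion(data):
    vals = data[data != -9999]
    classes = sorted(set(int(v) for v in vals))
    m = len(classes)
    if m == 1:
        return 100.0
    g = _cell_adjacencies(data)
    s = 0.0
    for i in classes:
        p_i = np.mean(vals == i)
        row = sum(g.get((i, k), 0) for k in classes)
        for k in classes:
            if row == 0:
                continue
            q = p_i * g.get((i, k), 0) / row
            if q > 0:
                s += q * math.log(q)
    return (1 + s / (2 * math.log(m))) * 100


def _oracle_perimeter(cells, cell_size=100.0):
    cellset = set(cells)
    per = 0
    for (r, c) in cells:
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            if (r + dr, c + dc) not in cellset:
                per += 1
    return per * cell_size


def _oracle_contiguity(cells):
    cellset = set(cells)
    weights = {(0, 0): 1, (0, 1): 2, (0, -1): 2, (1, 0): 2, (-1, 0): 2,
               (1, 1): 1, (1, -1): 1, (-1, 1): 1, (-1, -1): 1}
    total = 0.0
    for (r, c) in cells:
        total += sum(w for (dr, dc), w in weights.items() if (r + dr, c + dc) in cellset)
    return (total / len(cells) - 1.0) / 12.0


def _oracle_enn_connect(patches, cell_size=100.0, threshold=None):
    """Brute-force nearest-neighbour distances over all cell pairs."""
    by_class = {}
    for code, cells in patches:
        by_class.setdefault(code, []).append(cells)
    nn = []
    pair_d = []
    for code, plist in by_class.items():
        if len(plist) < 2:
            continue
        n = len(plist)
        d = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(i + 1, n):
                best = min(math.hypot(a[0] - b[0], a[1] - b[1])
                           for a in plist[i] for b in plist[j]) * cell_size
                d[i, j] = d[j, i] = best
                pair_d.append(best)
        nn.extend(d.min(axis=1))
    enn = float(np.mean(nn)) if nn else None
    if threshold is None or not pair_d:
        return enn, None
    conn = 100.0 * sum(1 for v in pair_d if v <= threshold) / len(pair_d)
    return enn, conn


# ------------------------------------------------------------- delineation

def test_uniform_raster_is_one_patch():
    p = delineate_patches(LandUseGrid(np.full((5, 7), 3)))
    assert p.n_patches == 1
    assert p.patches[0].area_hm2 == 35.0


def test_checkerboard_under_4_connectivity_is_all_singletons():
    data = (np.indices((6, 6)).sum(axis=0) % 2) + 1
    p4 = delineate_patches(LandUseGrid(data), connectivity=4)
    assert p4.n_patches == 36
    p8 = delineate_patches(LandUseGrid(data), connectivity=8)
    assert p8.n_patches == 2


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("connectivity", [4, 8])
def test_patch_count_matches_flood_fill_oracle(seed, connectivity):
    rng = np.random.default_rng(seed)
    data = rng.integers(1, 4, size=(20, 20))
    p = delineate_patches(LandUseGrid(data), connectivity=connectivity)
    oracle = _flood_fill_patches(data, connectivity)
    assert p.n_patches == len(oracle)
    assert sorted(q.n_cells for q in p.patches) == sorted(len(c) for _, c in oracle)


def test_empty_raster_rejected():
    with pytest.raises(ValueError, match="empty"):
        delineate_patches(LandUseGrid(np.full((3, 3), -9999)))


# ------------------------------------------------------------- simple stats

def test_mean_patch_size_and_cv():
    # 1×2 landscape of two singleton patches: areas (1, 1)
    p = delineate_patches(LandUseGrid(np.array([[1, 2]])))
    assert mean_patch_size(p) == 1.0
    assert patch_size_cv(p) == 0.0
    # areas (1, 3): mean 2, population SD 1 → CV 50 %
    p2 = delineate_patches(LandUseGrid(np.array([[1, 2, 2, 2]])))
    assert mean_patch_size(p2) == 2.0
    assert patch_size_cv(p2) == pytest.approx(50.0)
    single = delineate_patches(LandUseGrid(np.full((2, 2), 1)))
    with pytest.raises(ValueError):
        patch_size_cv(single)


def test_lsi_is_one_for_a_solid_square_and_grows_with_internal_edge():
    solid = delineate_patches(LandUseGrid(np.full((8, 8), 1)))
    assert landscape_shape_index(solid) == pytest.approx(1.0)
    # 2×2 landscape split into two 1×2 patches: E* = 800 + 200, √A = 200 m
    split = delineate_patches(LandUseGrid(np.array([[1, 2], [1, 2]])))
    assert landscape_shape_index(split) == pytest.approx(1.25)
    data = np.full((8, 8), 1)
    data[:, 4:] = 2
    two = delineate_patches(LandUseGrid(data))
    assert landscape_shape_index(two) > 1.0


def test_contiguity_closed_forms():
    # one-pixel patch → exactly 0
    lone = delineate_patches(LandUseGrid(np.array([[1]])))
    assert lone.patches[0].contiguity == 0.0
    # 1×3 patch: template scores 3, 5, 3 → ((11/3) − 1)/12 = 2/9
    strip = delineate_patches(LandUseGrid(np.full((1, 3), 1)))
    assert strip.patches[0].contiguity == pytest.approx(2.0 / 9.0)
    # large solid squares approach the limit of 1 from below
    vals = [delineate_patches(LandUseGrid(np.full((n, n), 1))).patches[0].contiguity
            for n in (5, 10, 50)]
    assert vals == sorted(vals)
    assert vals[-1] > 0.9
    assert all(v < 1.0 for v in vals)


def test_contiguity_am_is_area_weighted(rng):
    data = rng.integers(1, 4, size=(10, 10))
    p = delineate_patches(LandUseGrid(data))
    oracle = 0.0
    cells = {q.id: list(zip(q.rows.tolist(), q.cols.tolist())) for q in p.patches}
    for q in p.patches:
        assert q.contiguity == pytest.approx(_oracle_contiguity(cells[q.id]))
        oracle += q.area_hm2 * _oracle_contiguity(cells[q.id])
    assert contiguity_am(p) == pytest.approx(oracle / sum(q.area_hm2 for q in p.patches))


def test_patch_perimeters_match_side_counting(rng):
    data = rng.integers(1, 4, size=(9, 9))
    p = delineate_patches(LandUseGrid(data))
    for q in p.patches:
        cells = list(zip(q.rows.tolist(), q.cols.tolist()))
        assert q.perimeter_m == pytest.approx(_oracle_perimeter(cells))


# ------------------------------------------------------------- contagion

def test_single_class_contagion_is_100_by_convention():
    assert contagion(LandUseGrid(np.full((4, 4), 2))) == 100.0


def test_interspersion_lowers_contagion():
    # a well-mixed 50/50 map spreads adjacencies over all class pairs and
    # scores far below two solid halves of the same composition
    rng = np.random.default_rng(5)
    mixed = rng.permutation(np.repeat([1, 2], 32)).reshape(8, 8)
    halves = np.full((8, 8), 1)
    halves[:, 4:] = 2
    assert contagion(LandUseGrid(mixed)) < contagion(LandUseGrid(halves))
    # a two-class checkerboard concentrates all adjacency mass on the two
    # unlike pairs: the adjacency entropy is ln 2, half the maximum, so
    # the index sits at exactly 50
    checker = (np.indices((8, 8)).sum(axis=0) % 2) + 1
    assert contagion(LandUseGrid(checker)) == pytest.approx(50.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_contagion_matches_hand_tabulation(seed):
    rng = np.random.default_rng(seed)
    data = rng.integers(1, 4, size=(4, 4))
    got = contagion(LandUseGrid(data))
    assert got == pytest.approx(_oracle_contagion(data))


# ------------------------------------------------------------- distances

def test_two_singleton_patches_three_columns_apart():
    data = np.array([[1, 2, 2, 1]])
    p = delineate_patches(LandUseGrid(data))
    assert enn_mn(p) == pytest.approx(300.0)


def test_enn_undefined_when_all_classes_single_patch():
    p = delineate_patches(LandUseGrid(np.array([[1, 2]])))
    with pytest.raises(ValueError, match="ENN"):
        enn_mn(p)
    with pytest.raises(ValueError, match="connectance"):
        connectance(p, 100.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_enn_and_connectance_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    data = rng.integers(1, 4, size=(10, 10))
    p = delineate_patches(LandUseGrid(data))
    threshold = 250.0
    oracle_enn, oracle_conn = _oracle_enn_connect(
        [(q.class_code, list(zip(q.rows.tolist(), q.cols.tolist())))
         for q in p.patches], threshold=threshold)
    assert enn_mn(p) == pytest.approx(oracle_enn)
    assert connectance(p, threshold) == pytest.approx(oracle_conn)


def test_connectance_threshold_extremes():
    data = np.array([[1, 2, 2, 1], [2, 2, 2, 2]])
    p = delineate_patches(LandUseGrid(data))
    assert connectance(p, 1.0) == 0.0
    assert connectance(p, 1e6) == 100.0


def test_merging_two_nearest_patches_never_decreases_mean_enn():
    # three collinear singletons of one class at columns 0, 2, 7
    data = np.full((1, 9), 2)
    data[0, [0, 2, 7]] = 1
    before = enn_mn(delineate_patches(LandUseGrid(data)))
    merged = data.copy()
    merged[0, 1] = 1  # joins the two nearest patches
    after = enn_mn(delineate_patches(LandUseGrid(merged)))
    assert after >= before


# ------------------------------------------------------------- diversity

def test_shannon_closed_forms():
    single = LandUseGrid(np.full((4, 4), 5))
    assert shdi(single) == 0.0
    assert shei(single) == 0.0
    half = LandUseGrid(np.repeat([[1, 2]], 8, axis=0))
    assert shdi(half) == pytest.approx(math.log(2))
    assert shei(half) == pytest.approx(1.0)
    data = np.full((2, 4), 1)
    data[0, 2:] = 2
    data[1, 2:] = 3  # proportions (0.5, 0.25, 0.25)
    assert shdi(LandUseGrid(data)) == pytest.approx(1.5 * math.log(2))


# ------------------------------------------------------------- report level

def test_metric_bounds_hold_on_1000_random_rasters():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        m = rng.integers(2, 6)
        data = rng.integers(1, m + 1, size=(8, 8))
        grid = LandUseGrid(data)
        e = shei(grid)
        assert 0.0 <= e <= 1.0
        assert shdi(grid) >= 0.0
        # contagion reaches exactly 0 when adjacencies spread evenly
        c = contagion(grid)
        assert 0.0 <= c <= 100.0


def test_all_metrics_invariant_under_class_relabeling(rng):
    data = rng.integers(1, 5, size=(12, 12))
    perm = {1: 7, 2: 3, 3: 8, 4: 1}
    relabeled = np.vectorize(perm.get)(data)
    a = compute_metrics(LandUseGrid(data))
    b = compute_metrics(LandUseGrid(relabeled))
    for k, v in a.to_dict().items():
        assert v == pytest.approx(b.to_dict()[k]), k


def test_report_has_all_nine_metrics(study_run):
    report = compute_metrics(study_run.final)
    d = report.to_dict()
    assert set(d) == {
        "mean_patch_size", "patch_size_cv", "landscape_shape_index",
        "contiguity_am", "contagion", "enn_mn", "connectance", "shdi", "shei",
    }
    assert all(np.isfinite(v) for v in d.values())
    assert 0.0 <= d["contiguity_am"] <= 1.0
    assert 0.0 <= d["shei"] <= 1.0
    assert 0.0 < d["contagion"] <= 100.0
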