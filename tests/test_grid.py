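import numpy as np
import pytest

from gridshift.grid import GridDefinition, make_grid


def brute_force_edges(grid):
    """Undirected queen edges by exhaustive pair enumeration."""
    cells = grid.cells
    pos = list(zip(cells["row"], cells["col"]))
    edges = 0
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if max(abs(pos[i][0] - pos[j][0]),
                   abs(pos[i][1] - pos[j][1])) == 1:
                edges += 1
    return edges


def test_2x2_grid_every_cell_has_three_neighbours():
    g = make_grid(2, 2)
    assert all(len(nbs) == 3 for nbs in g.neighbours.values())


def test_3x3_grid_centre_and_corner_degrees():
    g = make_grid(3, 3)
    assert len(g.neighbours["r1c1"]) == 8
    for corner in ("r0c0", "r0c2", "r2c0", "r2c2"):
        assert len(g.neighbours[corner]) == 3


def test_directed_adjacency_count_matches_brute_force():
    g = make_grid(5, 4)
    directed = sum(len(nbs) for nbs in g.neighbours.values())
    assert directed == 2 * brute_force_edges(g)


def test_adjacency_symmetric_and_irreflexive(grid5):
    for cell, nbs in grid5.neighbours.items():
        assert cell not in nbs
        for nb in nbs:
            assert cell in grid5.neighbours[nb]
    assert len(set(grid5.cell_ids)) == grid5.n_cells


def test_adjacency_matrix_matches_neighbour_lists(grid5):
    W = grid5.adjacency_matrix().toarray()
    assert np.array_equal(W, W.T)
    for cell, nbs in grid5.neighbours.items():
        i = grid5.index_of(cell)
        assert W[i].sum() == len(nbs)


@pytest.mark.parametrize("shape", [(1, 5), (5, 1), (0, 3)])
def test_degenerate_dimensions_rejected(shape):
    with pytest.raises(ValueError):
        make_grid(*shape)


def test_csv_round_trip(tmp_path, grid5):
    path = tmp_path / "grid.csv"
    grid5.to_csv(path)
    back = GridDefinition.from_csv(path)
    assert back.neighbours == grid5.neighbours
    assert back.cell_ids == grid5.cell_ids
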