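import numpy as np

from colonyabc import LatticeState


def make_state(cells, n_rows=24, n_cols=32, tracked=()):
    """Build a validated lattice state from (col, row) coordinates."""
    cells = np.asarray(cells, dtype=np.int64).reshape(-1, 2)
    occ = np.zeros((n_rows, n_cols), dtype=bool)
    occ[cells[:, 1], cells[:, 0]] = True
    return LatticeState(
        occupancy=occ, cells=cells, tracked=np.asarray(tracked, dtype=np.int64)
    )
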