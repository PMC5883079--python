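import numpy as np
import pytest
from scipy.optimize import minimize

from crossnet_astm import (
    Movie,
    RecorderParams,
    build_grid,
    generate_movie,
    record_agd,
    record_dgd,
    record_hebb,
    record_qp,
    step_sync,
)
from crossnet_astm.recording import (
    load_weights_csv,
    load_weights_npz,
    pair_tensors,
    save_weights_csv,
    save_weights_npz,
)

# ---------------------------------------------------------------------------
# Independent reference implementations (slow, loop-based oracles)


def hebb_oracle(movie, grid):
    S = movie.flat().astype(float)
    W = np.zeros((grid.N, grid.M))
    for i in range(grid.N):
        for k, j in enumerate(grid.neighbor_table[i]):
            W[i, k] = sum(
                S[(q + 1) % movie.Q, i] * S[q, j] for q in range(movie.Q)
            ) / movie.Q
    return W


def agd_oracle_epochs(movie, grid, eta, n_epochs):
    S = movie.flat().astype(float)
    W = np.zeros((grid.N, grid.M))
    for _ in range(n_epochs):
        for q in range(movie.Q):
            nxt = S[(q + 1) % movie.Q]
            for i in range(grid.N):
                x = S[q, grid.neighbor_table[i]]
                eps = W[i] @ x - nxt[i]
                W[i] = W[i] - eta * eps * x
    return W


def dgd_oracle_epochs(movie, grid, eta, D, n_epochs):
    S = movie.flat().astype(float)
    W = np.zeros((grid.N, grid.M))
    errs = []
    for _ in range(n_epochs):
        for q in range(movie.Q):
            nxt = S[(q + 1) % movie.Q]
            for i in range(grid.N):
                x = S[q, grid.neighbor_table[i]]
                a = W[i] @ x
                Sout = 1.0 if a - D * nxt[i] >= 0 else -1.0
                eps = Sout - nxt[i]
                errs.append(eps)
                W[i] = W[i] - eta * eps * x
    return W, errs


def qp_oracle_cell(A, kappa):
    """Generic constrained least-norm via SLSQP."""
    M = A.shape[1]
    res = minimize(
        lambda w: 0.5 * w @ w,
        x0=np.zeros(M),
        jac=lambda w: w,
        constraints=[{"type": "ineq", "fun": lambda w: A @ w - kappa,
                      "jac": lambda w: A}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return res.x


# ---------------------------------------------------------------------------
# Hebb rule


def test_hebb_identical_frames(tiny_grid):
    frame = generate_movie(tiny_grid, 1, 0.5, 3).frames[0]
    movie = Movie(frames=np.repeat(frame[None], 5, axis=0))
    ws = record_hebb(movie, tiny_grid)
    s = frame.reshape(-1).astype(float)
    expected = s[:, None] * s[tiny_grid.neighbor_table]
    assert np.allclose(ws.W, expected)


def test_hebb_matches_loop_oracle(tiny_grid, tiny_movie):
    ws = record_hebb(tiny_movie, tiny_grid)
    assert np.allclose(ws.W, hebb_oracle(tiny_movie, tiny_grid))


def test_hebb_two_frame_formula(tiny_grid):
    movie = generate_movie(tiny_grid, 2, 0.5, 11)
    ws = record_hebb(movie, tiny_grid)
    S = movie.flat().astype(float)
    nbr = tiny_grid.neighbor_table
    expected = 0.5 * (S[1][:, None] * S[0][nbr] + S[0][:, None] * S[1][nbr])
    assert np.allclose(ws.W, expected)


def test_hebb_weight_bounds_and_parity(tiny_grid):
    for Q in (3, 4, 7):
        movie = generate_movie(tiny_grid, Q, 0.5, Q)
        ws = record_hebb(movie, tiny_grid)
        assert np.abs(ws.W).max() <= 1.0 + 1e-12
        scaled = ws.W * Q
        assert np.allclose(scaled, np.round(scaled))
        assert np.all((np.round(scaled).astype(int) - Q) % 2 == 0)


def test_hebb_cyclic_rotation_invariance(tiny_grid, tiny_movie):
    rolled = Movie(frames=np.roll(tiny_movie.frames, 2, axis=0))
    a = record_hebb(tiny_movie, tiny_grid)
    b = record_hebb(rolled, tiny_grid)
    assert np.allclose(a.W, b.W)


@pytest.mark.parametrize("rule", ["hebb", "qp", "agd", "dgd"])
def test_recording_translation_equivariance(rule):
    """Recording a translated movie translates the weight vectors."""
    g = build_grid(6, 6, 3)
    movie = generate_movie(g, 4, 0.5, 21)
    dr, dc = 2, 3
    shifted = Movie(frames=np.roll(movie.frames, (dr, dc), axis=(1, 2)))
    rec = {
        "hebb": lambda m: record_hebb(m, g),
        "qp": lambda m: record_qp(m, g)[0],
        "agd": lambda m: record_agd(m, g)[0],
        "dgd": lambda m: record_dgd(m, g)[0],
    }[rule]
    W1, W2 = rec(movie).W, rec(shifted).W
    perm = np.array(
        [g.cell_index(r + dr, c + dc) for r in range(6) for c in range(6)]
    )
    # cell i of the original corresponds to cell perm[i] of the shifted movie
    assert np.allclose(W2[perm], W1, atol=1e-9)


# ---------------------------------------------------------------------------
# Quadratic programming


def test_qp_single_pair_closed_form(tiny_grid):
    """Q=1 self-map: min-norm solution lies along the constraint normal."""
    frame = generate_movie(tiny_grid, 1, 0.5, 9).frames[0]
    movie = Movie(frames=frame[None])
    kappa = 1.0
    ws, report = record_qp(movie, tiny_grid, RecorderParams(rule="qp", kappa=kappa))
    assert report.feasible
    s = frame.reshape(-1).astype(float)
    expected = (kappa / tiny_grid.M) * s[:, None] * s[tiny_grid.neighbor_table]
    assert np.allclose(ws.W, expected, atol=1e-6)
    margins = s * (ws.W * s[tiny_grid.neighbor_table]).sum(axis=1)
    assert np.allclose(margins, kappa, atol=1e-6)


def test_qp_matches_generic_solver(tiny_grid):
    movie = generate_movie(tiny_grid, 3, 0.5, 17)
    ws, report = record_qp(movie, tiny_grid)
    assert report.feasible
    X, T = pair_tensors(movie, tiny_grid)
    for i in (0, 7, 19):
        A = (T[:, i, None] * X[:, i, :]).astype(float)
        expected = qp_oracle_cell(A, 1.0)
        assert np.allclose(ws.W[i], expected, atol=1e-4)


def test_qp_margins_feasible(small_grid):
    movie = generate_movie(small_grid, 12, 0.5, 23)
    params = RecorderParams(rule="qp")
    ws, report = record_qp(movie, small_grid, params)
    assert report.feasible
    X, T = pair_tensors(movie, small_grid)
    margins = np.einsum("qn,nm,qnm->qn", T.astype(float), ws.W, X.astype(float))
    assert margins.min() >= params.kappa - 1e-6


def test_qp_kappa_scaling(tiny_grid, tiny_movie):
    w1, _ = record_qp(tiny_movie, tiny_grid, RecorderParams(rule="qp", kappa=1.0))
    w3, _ = record_qp(tiny_movie, tiny_grid, RecorderParams(rule="qp", kappa=3.0))
    assert np.allclose(w3.W, 3.0 * w1.W, atol=1e-5)
    start = tiny_movie.frames[2]
    assert np.array_equal(step_sync(w1, start), step_sync(w3, start))


# ---------------------------------------------------------------------------
# Analog gradient descent


def test_agd_fixed_point_converges_immediately(tiny_grid):
    """Weights that already solve the analog equations receive no updates."""
    frame = generate_movie(tiny_grid, 1, 0.5, 31).frames[0]
    movie = Movie(frames=np.repeat(frame[None], 4, axis=0))
    # exact interpolating weights: w_ij = s_i s_j / M
    s = frame.reshape(-1).astype(float)
    ws0 = s[:, None] * s[tiny_grid.neighbor_table] / tiny_grid.M
    from crossnet_astm import _kernels

    X, T = pair_tensors(movie, tiny_grid)
    W = ws0.copy()
    epochs, err, converged, early = _kernels.agd_train(
        W, X, T.astype(float), 0.001, 0.1, 10, 0, 0
    )
    assert converged and epochs == 1 and err < 1e-12
    assert np.allclose(W, ws0)


def test_agd_scalar_recursion():
    """M=1 single-pair case follows w_k = s_i s_j (1 - (1-eta)^k) exactly."""
    from crossnet_astm import _kernels

    eta = 0.1
    x = np.full((1, 1, 1), -1.0)  # s_j = -1
    t = np.full((1, 1), 1.0)  # s_i = +1
    W = np.zeros((1, 1))
    for k in (1, 2, 5, 20):
        Wk = np.zeros((1, 1))
        _kernels.agd_train(Wk, x.astype(np.int8), t, eta, 1e-15, k, 0, 0)
        expected = (1.0 * -1.0) * (1 - (1 - eta) ** k)
        assert np.isclose(Wk[0, 0], expected)


def test_agd_matches_loop_oracle(tiny_grid, tiny_movie):
    from crossnet_astm import _kernels

    X, T = pair_tensors(tiny_movie, tiny_grid)
    W = np.zeros((tiny_grid.N, tiny_grid.M))
    _kernels.agd_train(W, X, T.astype(float), 0.01, 1e-15, 3, 0, 0)
    assert np.allclose(W, agd_oracle_epochs(tiny_movie, tiny_grid, 0.01, 3))


def test_agd_converges_subcapacity(small_grid):
    movie = generate_movie(small_grid, 12, 0.5, 5)  # Q = 0.5 M
    ws, report = record_agd(movie, small_grid)
    assert report.converged
    assert report.epochs_run < 100_000
    assert report.final_max_error < 0.1


# ---------------------------------------------------------------------------
# Discrete gradient descent


def test_dgd_single_update_hand_case():
    """w=(0,...), target +1, D=1: S=sgn(0-1)=-1, eps=-2, step +2 eta x."""
    from crossnet_astm import _kernels

    M = 8
    x = np.ones((1, 1, M), dtype=np.int8)
    x[0, 0, 1] = -1
    t = np.ones((1, 1))
    W = np.zeros((1, M))
    _kernels.dgd_train(W, x, t, 0.005, 1.0, 1)
    expected = 0.01 * x[0, 0].astype(float)
    assert np.allclose(W[0], expected)


def test_dgd_errors_ternary(tiny_grid, tiny_movie):
    _, errs = dgd_oracle_epochs(tiny_movie, tiny_grid, 0.005, 1.0, 2)
    assert set(errs) <= {-2.0, 0.0, 2.0}


def test_dgd_matches_loop_oracle(tiny_grid, tiny_movie):
    from crossnet_astm import _kernels

    X, T = pair_tensors(tiny_movie, tiny_grid)
    W = np.zeros((tiny_grid.N, tiny_grid.M))
    _kernels.dgd_train(W, X, T.astype(float), 0.005, 1.0, 2)
    expected, _ = dgd_oracle_epochs(tiny_movie, tiny_grid, 0.005, 1.0, 2)
    assert np.allclose(W, expected)


def test_dgd_convergence_certifies_margins(small_grid):
    movie = generate_movie(small_grid, 12, 0.5, 8)
    ws, report = record_dgd(movie, small_grid)
    assert report.converged
    X, T = pair_tensors(movie, small_grid)
    margins = np.einsum("qn,nm,qnm->qn", T.astype(float), ws.W, X.astype(float))
    # a_i s_i >= D for every cell and pair (equality only on the +1 side of
    # the sgn(0) = +1 tie-break), which guarantees exact one-step prediction
    assert margins.min() >= 1.0 - 1e-9
    assert margins.min() > 0.0


def test_dgd_gap_rescales_weights(small_grid):
    movie = generate_movie(small_grid, 8, 0.5, 13)
    w1, r1 = record_dgd(movie, small_grid, RecorderParams(rule="dgd", D=1.0))
    w2, r2 = record_dgd(movie, small_grid, RecorderParams(rule="dgd", D=2.0, eta=0.01))
    assert r1.converged and r2.converged
    assert np.allclose(w2.W, 2.0 * w1.W, atol=1e-12)
    start = movie.frames[0]
    assert np.array_equal(step_sync(w1, start), step_sync(w2, start))


def test_margin_satisfied_cell_not_updated():
    """a_i s_i > D implies S = s_i, zero error, no weight change."""
    from crossnet_astm import _kernels

    M = 4
    x = np.ones((1, 1, M), dtype=np.int8)
    t = np.ones((1, 1))
    W = np.full((1, M), 0.5)  # a = 2 > D = 1
    W0 = W.copy()
    epochs, n_err, converged = _kernels.dgd_train(W, x, t, 0.005, 1.0, 5)
    assert converged and n_err == 0
    assert np.array_equal(W, W0)


# ---------------------------------------------------------------------------
# Serialization


def test_weight_roundtrips(tmp_path, tiny_grid, tiny_movie):
    ws = record_hebb(tiny_movie, tiny_grid)
    save_weights_csv(tmp_path / "w.csv", ws)
    back = load_weights_csv(tmp_path / "w.csv")
    assert back.grid == tiny_grid and np.array_equal(back.W, ws.W)
    save_weights_npz(tmp_path / "w.npz", ws)
    back2 = load_weights_npz(tmp_path / "w.npz")
    assert back2.grid == tiny_grid and np.array_equal(back2.W, ws.W)
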