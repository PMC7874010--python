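"""Feature selection with orthogonal regression (FSOR).

The solver ranks features (genes) by fitting a weighted orthogonal
regression of the expression matrix onto a supervision (label) matrix:

    min_{W, b, phi}  || W^T Phi X + b 1_n^T - Y ||_F^2
    s.t.  W^T W = I_k,  phi >= 0,

where ``X`` is the d x n expression matrix, ``Phi = diag(phi)`` carries a
nonnegative importance weight per feature, ``W`` is a d x k orthogonal
projection and ``Y`` is a k x n label matrix built from survival status and
time.  Eliminating the bias ``b`` in closed form reduces the problem to

    min  || W^T Phi X M - Y M ||_F^2,   M = I_n - (1/n) 1 1^T,

which is solved by alternating two subproblems:

* the W-step, a quadratic program on the Stiefel manifold, solved by
  generalized power iteration (GPI);
* the phi-step, a nonnegative simplex-constrained quadratic program, solved
  by an augmented Lagrangian multiplier (ALM) method.

Features are then ranked by their fitted weights ``phi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "LabelMatrix",
    "FsorOptions",
    "FsorModel",
    "AlmResult",
    "build_label_matrix",
    "apply_centering",
    "fsor_objective",
    "solve_w_gpi",
    "solve_phi_alm",
    "fit_fsor",
    "rank_features",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Parameters
    ----------
    values : ndarray of shape (d, n)
        Log2-scale expression, one row per gene.
    gene_ids : list of str
        Unique gene identifiers, length d.
    sample_ids : list of str
        Unique sample identifiers, length n.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        d, n = self.values.shape
        if d < 1 or n < 2:
            raise ValueError(f"need >= 1 gene and >= 2 samples, got {d} x {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if len(self.gene_ids) != d:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes`` (in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), list(self.sample_ids))


@dataclass
class LabelMatrix:
    """Supervision matrix Y (k rows x n samples) for the FSOR objective."""

    values: np.ndarray
    row_labels: list[str]
    scheme: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("label matrix must be 2-D with k >= 1 rows")
        if len(self.row_labels) != self.values.shape[0]:
            raise ValueError("row_labels length does not match matrix rows")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class FsorOptions:
    """Solver knobs.

    ``outer_tol`` is the stopping rule on the change of the regression
    objective between consecutive outer iterations (default 0.1, on the
    objective's own scale).  The GPI and ALM tolerances control the two inner
    solvers; ``mu0``/``rho`` are the initial ALM penalty and its inflation
    factor; ``alpha_margin`` is the small relaxation that keeps the shifted
    quadratic in the W-step positive definite.
    """

    outer_tol: float = 0.1
    max_outer_iter: int = 1000
    gpi_tol: float = 1e-8
    gpi_max_iter: int = 500
    alm_tol: float = 1e-6
    alm_max_iter: int = 200
    mu0: float = 1.0
    rho: float = 1.1
    alpha_margin: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outer_tol", "gpi_tol", "alm_tol", "mu0", "alpha_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("max_outer_iter", "gpi_max_iter", "alm_max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.rho <= 1:
            raise ValueError("rho must be > 1")


@dataclass
class FsorModel:
    """A fitted FSOR model: projection W, feature weights phi, bias b."""

    W: np.ndarray
    phi: np.ndarray
    b: np.ndarray
    objective_trace: list[float]
    n_outer_iter: int
    converged: bool
    gene_ids: list[str]
    options: FsorOptions = field(default_factory=FsorOptions)
    # per outer iteration: (||W^T W - I||_F, min phi, |sum phi - 1|)
    feasibility_trace: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serializable summary (gene ids, weights, trace, options)."""
        from dataclasses import asdict

        return {
            "gene_ids": list(self.gene_ids),
            "phi": [float(v) for v in self.phi],
            "objective_trace": [float(v) for v in self.objective_trace],
            "n_outer_iter": self.n_outer_iter,
            "converged": self.converged,
            "options": asdict(self.options),
        }


@dataclass
class AlmResult:
    """Outcome of the augmented-Lagrangian phi-step."""

    phi: np.ndarray
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# Label matrix and centering
# ---------------------------------------------------------------------------


def build_label_matrix(clinical, scheme: str = "onehot_status_plus_time") -> LabelMatrix:
    """Build the supervision matrix Y from a clinical table.

    ``onehot_status_plus_time`` stacks the one-hot encoding of vital status
    (alive/censored, dead) with survival time min-max normalized to [0, 1]
    (k = 3).  ``onehot_status_only`` keeps just the two indicator rows
    (k = 2).  Columns follow the clinical table's row order.
    """
    times = np.asarray(clinical.time, dtype=float)
    status = np.asarray(clinical.status)
    if times.size < 2:
        raise ValueError("clinical table needs >= 2 samples")
    if not np.all(np.isfinite(times)) or np.any(times <= 0):
        raise ValueError("survival times must be finite and > 0")
    if not np.all(np.isin(status, (0, 1))):
        raise ValueError("status must be 0 (alive/censored) or 1 (dead)")
    status = status.astype(int)

    alive = (status == 0).astype(float)
    dead = (status == 1).astype(float)
    if scheme == "onehot_status_only":
        return LabelMatrix(np.vstack([alive, dead]), ["status=0", "status=1"], scheme)
    if scheme != "onehot_status_plus_time":
        raise ValueError(f"unknown label scheme: {scheme!r}")
    span = times.max() - times.min()
    if span <= 0:
        raise ValueError("constant survival times: min-max normalization degenerate")
    tnorm = (times - times.min()) / span
    return LabelMatrix(
        np.vstack([alive, dead, tnorm]),
        ["status=0", "status=1", "time_norm"],
        scheme,
    )


def apply_centering(A: np.ndarray) -> np.ndarray:
    """Right-multiply by the centering operator M = I - (1/n)11^T.

    Equivalent to subtracting each row's mean; M is never materialized, so
    the cost is O(size of A) rather than O(n^2).
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty matrix")
    if A.ndim == 1:
        return A - A.mean()
    return A - A.mean(axis=1, keepdims=True)


def fsor_objective(X, Y, W: np.ndarray, phi: np.ndarray) -> float:
    """The centered regression loss ||W^T Phi X M - Y M||_F^2.

    Equals the original objective minimized over the bias ``b`` (whose
    closed form is b = (1/n)(Y 1 - W^T Phi X 1)).
    """
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    Yv = Y.values if isinstance(Y, LabelMatrix) else np.asarray(Y, dtype=float)
    phi = np.asarray(phi, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(phi < 0):
        raise ValueError("phi must be nonnegative")
    if Xv.shape[1] != Yv.shape[1] or W.shape != (Xv.shape[0], Yv.shape[0]):
        raise ValueError("dimension mismatch between X, Y and W")
    if phi.shape != (Xv.shape[0],):
        raise ValueError("phi length must equal the number of features")
    R = W.T @ (phi[:, None] * apply_centering(Xv)) - apply_centering(Yv)
    return float(np.sum(R * R))


# ---------------------------------------------------------------------------
# W-step: generalized power iteration on the Stiefel manifold
# ---------------------------------------------------------------------------


def _check_stiefel(W: np.ndarray, tol: float = 1e-6) -> None:
    k = W.shape[1]
    if np.linalg.norm(W.T @ W - np.eye(k)) > tol:
        raise ValueError("W is not on the Stiefel manifold (W^T W != I)")


def solve_w_gpi(
    C: np.ndarray,
    D: np.ndarray,
    W0: np.ndarray,
    opts: FsorOptions | None = None,
) -> np.ndarray:
    """Minimize Tr(W^T C W - 2 W^T D) over W^T W = I_k by GPI.

    The problem is relaxed to maximizing Tr(W^T C~ W) + 2 Tr(W^T D) with
    C~ = alpha*I - C chosen positive definite (alpha slightly above the
    dominant eigenvalue of C).  Each sweep sets W to the polar factor
    U V^T of G = 2 C~ W + 2 D, which never decreases the relaxed objective.

    The iteration is only locally convergent (non-global fixed points can be
    attracting), so it is restarted from a small deterministic set of
    initial points — W0, the Procrustes polar factor of D, and the
    eigenvectors of the k smallest eigenvalues of C, each optimal in a
    limiting regime — and the best iterate is returned.
    """
    opts = opts or FsorOptions()
    C = np.asarray(C, dtype=float)
    D = np.asarray(D, dtype=float)
    W0 = np.asarray(W0, dtype=float)
    d, k = W0.shape
    if k > d:
        raise ValueError("k may not exceed d")
    if C.shape != (d, d) or np.linalg.norm(C - C.T) > 1e-8 * max(1.0, np.linalg.norm(C)):
        raise ValueError("C must be a symmetric d x d matrix")
    _check_stiefel(W0)

    eigvals, eigvecs = np.linalg.eigh(C)
    alpha = max(float(eigvals[-1]), 0.0) * (1.0 + opts.alpha_margin) + opts.alpha_margin
    Ct = alpha * np.eye(d) - C

    def relaxed(W):
        return float(np.trace(W.T @ Ct @ W) + 2.0 * np.trace(W.T @ D))

    starts = [W0.copy()]
    if np.linalg.norm(D) > 0:
        U, _, Vt = np.linalg.svd(D, full_matrices=False)
        starts.append(U @ Vt)
    starts.append(eigvecs[:, :k])

    best_W, best_val = None, -np.inf
    for W in starts:
        for _ in range(opts.gpi_max_iter):
            G = 2.0 * (Ct @ W) + 2.0 * D
            U, _, Vt = np.linalg.svd(G, full_matrices=False)
            W_next = U @ Vt
            done = np.linalg.norm(W_next - W) <= opts.gpi_tol
            W = W_next
            if done:
                break
        val = relaxed(W)
        if val > best_val:
            best_W, best_val = W, val
    return best_W


# ---------------------------------------------------------------------------
# phi-step: augmented Lagrangian for the nonnegative simplex QP
# ---------------------------------------------------------------------------


def solve_phi_alm(
    H: np.ndarray,
    r: np.ndarray,
    opts: FsorOptions | None = None,
) -> AlmResult:
    """Minimize phi^T H phi - phi^T r subject to phi >= 0, sum(phi) = 1.

    Augmented-Lagrangian scheme with a nonnegative slack ``v``:
    the phi update solves the linear system J phi = g with
    J = 2H + mu*I + mu*11^T and g = mu*v + mu*1 - lam2*1 - lam1 + r;
    the slack update projects phi + lam1/mu onto the nonnegative orthant;
    multipliers follow first-order updates and mu inflates by rho.
    """
    opts = opts or FsorOptions()
    H = np.asarray(H, dtype=float)
    r = np.asarray(r, dtype=float).ravel()
    d = r.size
    if H.shape != (d, d):
        raise ValueError("H and r dimensions do not match")
    if np.linalg.norm(H - H.T) > 1e-8 * max(1.0, np.linalg.norm(H)):
        raise ValueError("H must be symmetric")
    eigmin = float(np.linalg.eigvalsh(H)[0])
    if eigmin < -1e-8 * max(1.0, abs(float(np.linalg.eigvalsh(H)[-1]))):
        raise ValueError(f"H is not PSD (min eigenvalue {eigmin:.3e})")

    ones = np.ones(d)
    phi = np.full(d, 1.0 / d)
    v = phi.copy()
    lam1 = np.zeros(d)
    lam2 = 0.0
    mu = opts.mu0
    converged = False
    n_iter = 0
    best_phi, best_viol = phi.copy(), np.inf

    for n_iter in range(1, opts.alm_max_iter + 1):
        J = 2.0 * H + mu * np.eye(d) + mu * np.outer(ones, ones)
        g = mu * v + mu * ones - lam2 * ones - lam1 + r
        phi = np.linalg.solve(J, g)
        v = np.maximum(phi + lam1 / mu, 0.0)
        viol = max(float(np.max(np.abs(phi - v))), abs(float(phi @ ones) - 1.0))
        if viol < best_viol:
            best_viol, best_phi = viol, phi.copy()
        lam1 = lam1 + mu * (phi - v)
        lam2 = lam2 + mu * (float(phi @ ones) - 1.0)
        mu *= opts.rho
        if viol <= opts.alm_tol:
            converged = True
            break

    phi = np.maximum(best_phi, 0.0)
    total = phi.sum()
    if total <= 0:
        phi = np.full(d, 1.0 / d)
    else:
        phi = phi / total
    return AlmResult(phi=phi, converged=converged, n_iter=n_iter)


# ---------------------------------------------------------------------------
# Outer alternation
# ---------------------------------------------------------------------------


def fit_fsor(X, Y, opts: FsorOptions | None = None) -> FsorModel:
    """Fit the FSOR model by alternating the W-step (GPI) and phi-step (ALM).

    phi starts uniform (1/d); W starts from a seeded QR factor of a
    standard-normal draw.  The outer loop stops when the centered objective
    changes by at most ``opts.outer_tol`` between consecutive iterations.
    """
    opts = opts or FsorOptions()
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    Yv = Y.values if isinstance(Y, LabelMatrix) else np.asarray(Y, dtype=float)
    gene_ids = (
        list(X.gene_ids)
        if isinstance(X, ExpressionMatrix)
        else [f"g{i}" for i in range(Xv.shape[0])]
    )
    d, n = Xv.shape
    k = Yv.shape[0]
    if Yv.shape[1] != n:
        raise ValueError("X and Y sample counts differ")
    if n < 2:
        raise ValueError("need at least 2 samples")

    rng = np.random.default_rng(opts.seed)
    Wq, _ = np.linalg.qr(rng.standard_normal((d, k)))
    W = Wq[:, :k]
    phi = np.full(d, 1.0 / d)

    Xc = apply_centering(Xv)  # X M
    Yc = apply_centering(Yv)  # Y M
    XcYt = Xc @ Yc.T  # d x k, reused by both subproblem builders
    gram = Xc @ Xc.T  # d x d, the data Gram matrix X M X^T

    def objective(W_, phi_):
        R = W_.T @ (phi_[:, None] * Xc) - Yc
        return float(np.sum(R * R))

    trace = [objective(W, phi)]
    feas: list[tuple[float, float, float]] = []
    converged = False
    n_outer = 0
    for n_outer in range(1, opts.max_outer_iter + 1):
        # W-step: C = Phi X M X^T Phi, D = Phi X M Y^T for the current phi
        PX = phi[:, None] * Xc
        C = PX @ PX.T
        D = phi[:, None] * XcYt
        W = solve_w_gpi(C, D, W, opts)

        # phi-step: H = (X M X^T) o (W W^T), r = diag(2 X M Y^T W^T)
        H = gram * (W @ W.T)
        r = 2.0 * np.einsum("ij,ij->i", XcYt, W)
        cand = solve_phi_alm(H, r, opts).phi
        # ALM is inexact: accept the candidate only if it does not worsen
        # the objective beyond the inner tolerance
        if objective(W, cand) <= objective(W, phi) + opts.alm_tol:
            phi = cand

        obj = objective(W, phi)
        if not np.isfinite(obj):
            raise FloatingPointError("FSOR objective became non-finite")
        trace.append(obj)
        feas.append(
            (
                float(np.linalg.norm(W.T @ W - np.eye(k))),
                float(phi.min()),
                abs(float(phi.sum()) - 1.0),
            )
        )
        if abs(trace[-2] - trace[-1]) <= opts.outer_tol:
            converged = True
            break

    b = (Yv.sum(axis=1) - W.T @ (phi[:, None] * Xv) @ np.ones(n)) / n
    return FsorModel(
        W=W,
        phi=phi,
        b=b,
        objective_trace=trace,
        n_outer_iter=n_outer,
        converged=converged,
        gene_ids=gene_ids,
        options=opts,
        feasibility_trace=feas,
    )


def rank_features(model: FsorModel, top_m: int) -> list[tuple[str, float]]:
    """Top ``top_m`` genes by weight, descending; ties broken by gene id."""
    d = len(model.gene_ids)
    if not 1 <= top_m <= d:
        raise ValueError(f"top_m must be in [1, {d}]")
    order = sorted(
        range(d), key=lambda i: (-float(model.phi[i]), model.gene_ids[i])
    )
    return [(model.gene_ids[i], float(model.phi[i])) for i in order[:top_m]]
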