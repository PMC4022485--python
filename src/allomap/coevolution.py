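"""Pairwise residue-coevolution scorers on a common interface.

Five complementary statistics of correlated substitution between
alignment columns, each returning a symmetric column×column score
matrix wrapped in :class:`CoevolutionResult`:

* **MIp** — mutual information with the Average Product Correction
  (APC), which subtracts the background signal a column shares with
  every other column (phylogeny, conservation).
* **OMES** — observed-minus-expected-squared covariance of the pair
  count table, a chi-square-like statistic robust to small counts.
* **SCA** — statistical coupling analysis: covariance of residue
  indicator variables weighted by a conservation-derived positional
  weight, so couplings between conserved positions are emphasised.
* **DI** — direct information from mean-field direct coupling
  analysis; inverts the correlation matrix to disentangle direct
  couplings from transitive correlation chains.
* **PSICOV-style** — sparse inverse-covariance estimation (graphical
  lasso) on the indicator covariance matrix; like DI it removes
  indirect couplings, with an L1 penalty enforcing sparsity.

Gap convention: gaps are excluded (frequencies renormalised over the
amino acids present) for MI, OMES and SCA, and treated as a 21st state
for DI and PSICOV, matching the conventions of the originating methods.
MI/OMES/SCA run unweighted by default; DI/PSICOV use the alignment's
redundancy weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso

from .msa import (
    GAP_STATE,
    N_STATES,
    AlignmentSet,
    FrequencyTables,
    frequencies,
)

__all__ = [
    "CoevolutionResult",
    "mutual_information",
    "apc_correct",
    "mip",
    "omes",
    "sca",
    "direct_information",
    "psicov_score",
    "METHODS",
    "run_method",
]

#: Background amino-acid frequencies (order = msa.ALPHABET without gap),
#: the usual reference distribution for SCA positional weights.
BACKGROUND_FREQS = np.array(
    [
        0.073, 0.025, 0.050, 0.061, 0.042, 0.072, 0.023, 0.053, 0.064, 0.089,
        0.023, 0.043, 0.052, 0.040, 0.052, 0.073, 0.056, 0.063, 0.013, 0.033,
    ]
)


@dataclass
class CoevolutionResult:
    """Symmetric L×L coevolution score matrix plus metadata.

    The diagonal is a NaN sentinel and is excluded from all ranking.
    ``column_map`` carries the alignment's column→reference-residue map
    so scores can be addressed by structure residue ids downstream.
    """

    method: str
    scores: np.ndarray
    column_map: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape[0] != s.shape[1]:
            raise ValueError("score matrix must be square")
        off = ~np.eye(s.shape[0], dtype=bool)
        if not np.allclose(s[off], s.T[off], equal_nan=True):
            raise ValueError("score matrix must be symmetric")
        np.fill_diagonal(s, np.nan)
        self.scores = s

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]


def _pair_tensor(ft: FrequencyTables) -> np.ndarray:
    """f_ij reshaped to (L, q, L, q)."""
    length = ft.n_columns
    return ft.f_ij.reshape(length, N_STATES, length, N_STATES)


def _gapless_joint(ft: FrequencyTables) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair 20×20 joint distributions over non-gap pairs.

    Returns (P, valid_mass): P[i,:,j,:] is the joint table of columns
    i, j renormalised over sequences that are non-gap at both, and
    valid_mass[i, j] the fraction of (weighted) sequences retained.
    """
    t = _pair_tensor(ft)[:, :GAP_STATE, :, :GAP_STATE]
    mass = t.sum(axis=(1, 3))
    safe = np.where(mass > 0, mass, 1.0)
    return t / safe[:, None, :, None], mass


def mutual_information(ft: FrequencyTables) -> CoevolutionResult:
    """MI(i,j) = Σ_ab f_ij ln(f_ij / (f_i f_j)) over non-gap pairs (nats)."""
    p, mass = _gapless_joint(ft)
    pi = p.sum(axis=3)  # (L, 20, L)
    pj = p.sum(axis=1)  # (L, L, 20)
    denom = pi[:, :, :, None] * pj[:, None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / np.where(denom > 0, denom, 1.0)), 0.0)
    mi = terms.sum(axis=(1, 3))
    mi[mass <= 0] = np.nan  # no jointly non-gap sequences: undefined
    mi = np.maximum(0.5 * (mi + mi.T), 0.0)
    return CoevolutionResult("MI", mi, ft.column_map, {"pseudocount": ft.pseudocount})


def apc_correct(result: CoevolutionResult) -> CoevolutionResult:
    """Average Product Correction: S'(i,j) = S(i,j) − S̄_i S̄_j / S̄.

    Row means and the grand mean exclude the diagonal.  The correction
    removes the separable background component (a column's average
    coupling to everything), which is dominated by phylogeny and
    conservation rather than by specific pair constraints.  Corrected
    scores can be negative.
    """
    s = result.scores.copy()
    n = s.shape[0]
    if n < 3:
        warnings.warn("APC is degenerate for L < 3; returning zeros")
        out = np.zeros_like(s)
        return CoevolutionResult(
            result.method + "p", out, result.column_map, dict(result.params, apc=True)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row = np.nanmean(s, axis=1)
        grand = np.nanmean(s)
    if grand == 0 or not np.isfinite(grand):
        corrected = np.nan_to_num(s)
    else:
        corrected = s - np.outer(row, row) / grand
    return CoevolutionResult(
        result.method + ("p" if result.method == "MI" else "_apc"),
        np.nan_to_num(corrected),
        result.column_map,
        dict(result.params, apc=True),
    )


def mip(msa: AlignmentSet, pseudocount: float = 0.0, weighted: bool = False) -> CoevolutionResult:
    """APC-corrected mutual information (MIp)."""
    ft = frequencies(msa, pseudocount, weighted=weighted)
    return apc_correct(mutual_information(ft))


def omes(msa: AlignmentSet, weighted: bool = False) -> CoevolutionResult:
    """Observed-minus-expected-squared covariance.

    For each column pair, over the N_valid sequences that are non-gap
    at both columns: OMES(i,j) = Σ_ab (N_obs(a,b) − N_ex(a,b))² /
    N_valid with N_ex = N_valid f_i(a) f_j(b), the marginals taken on
    the same valid subset.
    """
    ft = frequencies(msa, 0.0, weighted=weighted)
    p, mass = _gapless_joint(ft)
    n_valid = mass * ft.m_eff
    pi = p.sum(axis=3)
    pj = p.sum(axis=1)
    expected = pi[:, :, :, None] * pj[:, None, :, :]
    score = ((p - expected) ** 2).sum(axis=(1, 3)) * n_valid
    score[mass <= 0] = np.nan
    score = 0.5 * (score + score.T)
    return CoevolutionResult("OMES", score, ft.column_map, {"weighted": weighted})


def sca(
    msa: AlignmentSet,
    background_freqs: np.ndarray | None = None,
    pseudocount_frac: float = 0.03,
    weighted: bool = False,
) -> CoevolutionResult:
    """Statistical coupling analysis (positional-weight covariance form).

    Indicator frequencies f_i(a) (gap contributes no indicator) are
    regularised toward the background and converted to positional
    weights φ_i(a) = |ln( f_i(a)(1−q_a) / ((1−f_i(a)) q_a) )|, large
    where a residue is unusually conserved relative to background.  The
    score is the Frobenius norm of the φ-weighted covariance block:
    C_ij = ‖ φ_i(a) φ_j(b) ( f_ij(a,b) − f_i(a) f_j(b) ) ‖_F.
    """
    q = BACKGROUND_FREQS if background_freqs is None else np.asarray(background_freqs)
    if len(q) != GAP_STATE:
        raise ValueError("background frequencies must cover the 20 amino acids")
    ft = frequencies(msa, 0.0, weighted=weighted)
    lam = pseudocount_frac
    raw1 = ft.f_i[:, :GAP_STATE]
    raw2 = _pair_tensor(ft)[:, :GAP_STATE, :, :GAP_STATE]
    # pseudocount regularises the positional weights only; the covariance
    # uses raw frequencies so invariant (e.g. fully conserved) columns
    # contribute exactly zero
    f1 = (1 - lam) * raw1 + lam * q[None, :]
    phi = np.abs(np.log(f1 * (1 - q[None, :]) / ((1 - f1) * q[None, :])))
    cov = raw2 - raw1[:, :, None, None] * raw1[None, None, :, :]
    weighted_cov = phi[:, :, None, None] * phi[None, None, :, :] * cov
    score = np.sqrt((weighted_cov**2).sum(axis=(1, 3)))
    score = 0.5 * (score + score.T)
    return CoevolutionResult(
        "SCA", score, ft.column_map, {"pseudocount_frac": lam, "weighted": weighted}
    )


def _pseudocounted_21state(
    msa: AlignmentSet, pseudocount_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted 21-state frequencies with relative pseudocount α.

    f_i = (1−α) f̂_i + α/q; pair tables analogously with α/q², except
    the i=i diagonal blocks which stay consistent with the single-site
    tables (f_ii(a,b) = δ_ab f_i(a) form).
    """
    alpha = pseudocount_frac
    q = N_STATES
    ft = frequencies(msa, 0.0, weighted=True)
    f_i = (1 - alpha) * ft.f_i + alpha / q
    f_ij = (1 - alpha) * ft.f_ij + alpha / q**2
    length = ft.n_columns
    t = f_ij.reshape(length, q, length, q)
    for i in range(length):
        t[i, :, i, :] = np.diag(f_i[i])
    return f_i, t.reshape(length * q, length * q)


def direct_information(
    msa: AlignmentSet,
    pseudocount_frac: float = 0.5,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> CoevolutionResult:
    """Direct information from mean-field direct coupling analysis.

    Couplings are obtained by the mean-field inversion e_ij(a,b) =
    −(C⁻¹)_ij(a,b) of the connected correlation matrix C_ij(a,b) =
    f_ij(a,b) − f_i(a) f_j(b) on the (q−1)-state reduction (gap is the
    reference state).  For each pair the two-site distribution
    P_ij(a,b) ∝ exp(e_ij(a,b)) h_i(a) h_j(b) is fit so its marginals
    match f_i, f_j, and DI(i,j) is the KL divergence of P_ij from the
    independent model — hence symmetric and ≥ 0.

    Gaps count as the 21st state; sequences must carry redundancy
    weights for the usual DCA behaviour.  The default pseudocount
    fraction of 0.5 regularises the inversion.
    """
    q = N_STATES
    length = msa.n_columns
    f_i, f_ij = _pseudocounted_21state(msa, pseudocount_frac)
    qm1 = q - 1
    idx = np.concatenate([np.arange(i * q, i * q + qm1) for i in range(length)])
    c_full = f_ij - np.outer(f_i.ravel(), f_i.ravel())
    c = c_full[np.ix_(idx, idx)]
    try:
        inv_c = np.linalg.inv(c)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "correlation matrix singular; increase pseudocount_frac"
        ) from None
    # couplings, padded back to q states (reference state row/col = 0)
    e_w = np.ones((length, q, length, q))
    inv_t = inv_c.reshape(length, qm1, length, qm1)
    for i in range(length):
        inv_t[i, :, i, :] = 0.0  # self-couplings are not pair couplings
    e_w[:, :qm1, :, :qm1] = np.exp(-inv_t)

    iu, ju = np.triu_indices(length, k=1)
    w = e_w[iu, :, ju, :]  # (n_pairs, q, q)
    fi = f_i[iu]
    fj = f_i[ju]
    mu1 = np.full_like(fi, 1.0 / q)
    mu2 = np.full_like(fj, 1.0 / q)
    converged = False
    for _ in range(max_iter):
        s1 = np.einsum("pab,pb->pa", w, mu2)
        new1 = fi / s1
        new1 /= new1.sum(axis=1, keepdims=True)
        s2 = np.einsum("pab,pa->pb", w, new1)
        new2 = fj / s2
        new2 /= new2.sum(axis=1, keepdims=True)
        delta = max(np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max())
        mu1, mu2 = new1, new2
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"two-site marginal matching did not converge: residual {delta:.2e} "
            f"after {max_iter} iterations"
        )
    p_dir = mu1[:, :, None] * w * mu2[:, None, :]
    p_dir /= p_dir.sum(axis=(1, 2), keepdims=True)
    indep = fi[:, :, None] * fj[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p_dir > 0, p_dir * np.log(p_dir / indep), 0.0)
    di_vals = np.maximum(terms.sum(axis=(1, 2)), 0.0)
    di = np.zeros((length, length))
    di[iu, ju] = di_vals
    di += di.T
    return CoevolutionResult(
        "DI",
        di,
        msa.column_map,
        {"pseudocount_frac": pseudocount_frac, "m_eff": float(msa.weights.sum())},
    )


def psicov_score(
    msa: AlignmentSet,
    lasso_rho: float = 0.005,
    state_min_freq: float = 0.01,
    max_density: float = 0.25,
    max_iter: int = 50,
    tol: float = 5e-3,
    apply_apc: bool = True,
) -> CoevolutionResult:
    """Sparse inverse-covariance (PSICOV-style) coupling scores.

    The weighted indicator covariance over the 21 states (gap included)
    is shrunk toward its diagonal until positive definite and handed to
    the graphical lasso; the pair score is the L1 block norm
    Σ_{a,b ≠ gap} |Θ_ij(a,b)| of the estimated precision matrix,
    followed by APC.  Per column, amino-acid states rarer than
    ``state_min_freq`` are pooled into a single state, which keeps the
    problem dimension (and the lasso runtime) proportional to the
    states actually carrying signal.  If the estimated precision is
    denser than ``max_density`` off the diagonal, the penalty is
    doubled and the fit repeated (sparsity guard).
    """
    length = msa.n_columns
    w = msa.weights
    m_eff = w.sum()
    ft = frequencies(msa, 0.0, weighted=True)
    # per-column state pools: frequent amino acids kept, rare ones pooled;
    # gap always its own state
    state_of: list[np.ndarray] = []
    kept_dims: list[int] = []
    gap_dim: list[int] = []
    for i in range(length):
        freq = ft.f_i[i]
        recode = np.full(N_STATES, -1, dtype=int)
        nxt = 0
        for a in range(GAP_STATE):
            if freq[a] >= state_min_freq:
                recode[a] = nxt
                nxt += 1
        pooled = nxt
        has_pool = np.any(recode[:GAP_STATE] < 0)
        if has_pool:
            recode[:GAP_STATE][recode[:GAP_STATE] < 0] = pooled
            nxt += 1
        recode[GAP_STATE] = nxt
        gap_dim.append(nxt)
        nxt += 1
        state_of.append(recode)
        kept_dims.append(nxt)
    offsets = np.concatenate([[0], np.cumsum(kept_dims)])
    dim = int(offsets[-1])
    n = msa.n_sequences
    onehot = np.zeros((n, dim), dtype=float)
    for i in range(length):
        codes = state_of[i][msa.matrix[:, i]]
        onehot[np.arange(n), offsets[i] + codes] = 1.0
    mean = (w[:, None] * onehot).sum(axis=0) / m_eff
    cov = (onehot * w[:, None]).T @ onehot / m_eff - np.outer(mean, mean)
    # shrink toward the diagonal until decently conditioned: the indicator
    # states of a column sum to one, so the raw covariance is exactly
    # singular and the lasso solver needs real eigenvalue mass at the bottom
    diag = np.diag(np.diag(cov))
    floor = 1e-3 * float(np.mean(np.diag(cov)))
    shrink = 0.0
    while True:
        shrunk = (1 - shrink) * cov + shrink * (diag + floor * np.eye(dim))
        if np.linalg.eigvalsh(shrunk)[0] > floor * shrink * 0.5:
            if shrink > 0.0:
                break
        shrink += 0.05
        if shrink > 1.0 + 1e-9:
            raise np.linalg.LinAlgError("covariance could not be made positive definite")
    rho = lasso_rho
    prec = None
    for _attempt in range(6):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = graphical_lasso(
                    shrunk, alpha=rho, max_iter=max_iter, tol=tol
                )
        except FloatingPointError:
            # coordinate descent lost positive definiteness: shrink harder
            # toward the diagonal and raise the penalty, then refit
            shrink = min(1.0, shrink + 0.10)
            shrunk = (1 - shrink) * cov + shrink * (diag + floor * np.eye(dim))
            rho *= 2.0
            continue
        off_mask = ~np.eye(dim, dtype=bool)
        density = float((np.abs(prec[off_mask]) > 1e-8).mean())
        if density <= max_density:
            break
        rho *= 2.0
    if prec is None:
        raise np.linalg.LinAlgError(
            "graphical lasso failed to converge to a positive-definite "
            "precision matrix even after shrinkage/penalty escalation"
        )
    score = np.zeros((length, length))
    for i in range(length):
        bi = slice(offsets[i], offsets[i + 1])
        for j in range(i + 1, length):
            bj = slice(offsets[j], offsets[j + 1])
            block = np.abs(prec[bi, bj])
            # exclude gap rows/cols from the block norm
            rows = [r for r in range(kept_dims[i]) if r != gap_dim[i]]
            cols = [c for c in range(kept_dims[j]) if c != gap_dim[j]]
            score[i, j] = block[np.ix_(rows, cols)].sum()
    score += score.T
    result = CoevolutionResult(
        "PSICOV",
        score,
        msa.column_map,
        {
            "lasso_rho": rho,
            "shrink": shrink,
            "state_min_freq": state_min_freq,
            "density": density,
        },
    )
    return apc_correct(result) if apply_apc else result


def _mip_entry(msa: AlignmentSet, **kw) -> CoevolutionResult:
    res = mip(msa, **kw)
    res.method = "MIp"
    return res


#: Registry of the five scorers under their field names.
METHODS = {
    "MIp": _mip_entry,
    "OMES": omes,
    "SCA": sca,
    "DI": direct_information,
    "PSICOV": psicov_score,
}


def run_method(name: str, msa: AlignmentSet, **kwargs) -> CoevolutionResult:
    """Run one of the five scorers by name."""
    if name not in METHODS:
        raise KeyError(f"unknown method {name!r}; available: {sorted(METHODS)}")
    result = METHODS[name](msa, **kwargs)
    result.method = name
    return result
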