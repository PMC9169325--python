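"""Ancestral intron content and per-branch loss/gain events.

Two routes are provided.  Dollo parsimony places each site's origin at the
most recent common ancestor of the intron-bearing species and drops the
intron on the minimal set of branches explaining all confirmed absences.
The likelihood route models each site as a two-state (absent/present)
continuous-time Markov chain with global gain and loss rates scaled by
branch length; the rate-variation flavour mixes two equal-prior loss-rate
categories (multipliers constrained to mean 1) over a single gain category.
Site likelihoods are conditioned on the site being observable (present in at
least one species), matching how presence/absence tables are built.  A
likelihood-ratio test compares the two flavours, and an up-down pass turns
the fitted model into per-branch event posteriors that are thresholded
(default 0.99) into an event history.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mapping import IntronSiteMatrix
from .phylo import TreeIndex

logger = logging.getLogger(__name__)

# reference anchor for density scaling: C. elegans in the ortholog set
CELEGANS_DENSITY = 3.65
CELEGANS_INTRON_COUNT = 373

RATE_FLOOR = 1e-9
RATE_CEIL = 1e2


@dataclass(frozen=True)
class RateModel:
    """Global two-state rates, optionally with two loss-rate categories."""

    kind: str = "constant"            # "constant" | "rate_variation"
    loss_rate: float = 0.5
    gain_rate: float = 0.1
    loss_multipliers: tuple[float, ...] = (1.0,)
    category_prior: tuple[float, ...] = (1.0,)
    root_prior: float | None = None   # P(present at root); None = stationary

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "rate_variation"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.loss_rate < 0 or self.gain_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.root_prior is not None and not 0 <= self.root_prior <= 1:
            raise ValueError("root_prior must lie in [0, 1]")
        if any(m <= 0 for m in self.loss_multipliers):
            raise ValueError("loss multipliers must be > 0")
        if abs(sum(self.category_prior) - 1.0) > 1e-9:
            raise ValueError("category priors must sum to 1")
        if len(self.loss_multipliers) != len(self.category_prior):
            raise ValueError("one prior per category required")

    @classmethod
    def rate_variation(
        cls,
        loss_rate: float,
        gain_rate: float,
        multiplier: float,
        root_prior: float | None = None,
    ) -> "RateModel":
        """Two loss categories with multipliers (m, 2-m), equal prior."""
        if not 0 < multiplier < 2:
            raise ValueError("multiplier must lie in (0, 2)")
        return cls(
            kind="rate_variation",
            loss_rate=loss_rate,
            gain_rate=gain_rate,
            loss_multipliers=(multiplier, 2.0 - multiplier),
            category_prior=(0.5, 0.5),
            root_prior=root_prior,
        )


@dataclass
class EventHistory:
    """Per-site origins and events plus per-branch and per-node summaries."""

    method: str
    site_origin: dict[str, str | None]
    site_losses: dict[str, list[str]]
    site_gain: dict[str, str | None]          # gaining branch (child label) or None
    branch_losses: dict[str, int]
    branch_gains: dict[str, int]
    node_counts: dict[str, float]             # ancestral present-site counts
    event_posteriors: pd.DataFrame | None = None

    @property
    def total_losses(self) -> int:
        return int(sum(self.branch_losses.values()))

    @property
    def total_gains(self) -> int:
        return int(sum(self.branch_gains.values()))

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for sid, branches in self.site_losses.items():
            rows.extend({"site_id": sid, "branch": b, "event": "loss"} for b in branches)
        for sid, b in self.site_gain.items():
            if b is not None:
                rows.append({"site_id": sid, "branch": b, "event": "gain"})
        return pd.DataFrame(rows, columns=["site_id", "branch", "event"])


def _matrix_codes(matrix: IntronSiteMatrix, tree: TreeIndex) -> np.ndarray:
    """Sites x leaves int codes: 1 present, 0 absent, -1 ambiguous."""
    missing = [sp for sp in matrix.species if sp not in tree.leaf_labels]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    tab = matrix.table[ [sp for sp in tree.leaf_labels if sp in matrix.table.columns] ]
    if list(tab.columns) != tree.leaf_labels:
        raise ValueError("matrix must cover every tree leaf")
    arr = np.full(tab.shape, -1, dtype=int)
    arr[tab.to_numpy() == "1"] = 1
    arr[tab.to_numpy() == "0"] = 0
    return arr


# ---------------------------------------------------------------------------
# Dollo parsimony


def dollo_events(matrix: IntronSiteMatrix, tree: TreeIndex) -> EventHistory:
    """Single-gain / minimal-loss reconstruction per site.

    The origin is the MRCA of the present leaves; each loss is placed on the
    highest branch inside the origin clade whose subtree holds confirmed
    absences and no presence.  Ambiguous cells impose no constraint.
    """
    codes = _matrix_codes(matrix, tree)
    leaf_of_col = [tree.index_of[sp] for sp in tree.leaf_labels]
    site_origin: dict[str, str | None] = {}
    site_losses: dict[str, list[str]] = {}
    site_gain: dict[str, str | None] = {}
    branch_losses = {tree.labels[i]: 0 for i in range(tree.n_nodes) if i != tree.root}
    branch_gains = {tree.labels[i]: 0 for i in range(tree.n_nodes) if i != tree.root}
    node_counts = {tree.labels[i]: 0.0 for i in range(tree.n_nodes)}

    for row, sid in enumerate(matrix.table.index):
        states = codes[row]
        present_nodes = [leaf_of_col[i] for i in range(len(states)) if states[i] == 1]
        if not present_nodes:
            raise ValueError(f"{sid}: no present species (all-absent rows are invalid)")
        origin = tree.mrca(present_nodes)
        site_origin[sid] = tree.labels[origin]
        gain_branch = None
        if origin != tree.root:
            gain_branch = tree.labels[origin]
            branch_gains[gain_branch] += 1
        site_gain[sid] = gain_branch

        has_present = np.zeros(tree.n_nodes, dtype=bool)
        has_absent = np.zeros(tree.n_nodes, dtype=bool)
        state_of = {leaf_of_col[i]: states[i] for i in range(len(states))}
        for node in tree.postorder:
            if tree.is_leaf[node]:
                has_present[node] = state_of[node] == 1
                has_absent[node] = state_of[node] == 0
            else:
                for c in tree.children[node]:
                    has_present[node] |= has_present[c]
                    has_absent[node] |= has_absent[c]
        losses: list[str] = []
        lost_under = np.zeros(tree.n_nodes, dtype=bool)
        stack = list(tree.children[origin])
        while stack:
            v = stack.pop()
            if not has_present[v]:
                if has_absent[v]:
                    losses.append(tree.labels[v])
                    branch_losses[tree.labels[v]] += 1
                    lost_under[v] = True
                continue  # no presence below: either a loss or unconstrained
            stack.extend(tree.children[v])
        site_losses[sid] = sorted(losses)

        # ancestral presence: inside origin clade, above every loss branch
        loss_set = {tree.index_of[b] for b in losses}
        stack = [origin]
        while stack:
            v = stack.pop()
            if v in loss_set:
                continue
            node_counts[tree.labels[v]] += 1.0
            stack.extend(tree.children[v])

    return EventHistory(
        method="dollo",
        site_origin=site_origin,
        site_losses=site_losses,
        site_gain=site_gain,
        branch_losses=branch_losses,
        branch_gains=branch_gains,
        node_counts=node_counts,
    )


# ---------------------------------------------------------------------------
# likelihood machinery


def _transition(loss: float, gain: float, t: float) -> np.ndarray:
    """2x2 branch transition matrix, states (0 absent, 1 present)."""
    p01 = 1.0 - np.exp(-gain * t)
    p10 = 1.0 - np.exp(-loss * t)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _root_prior(loss: float, gain: float, root_prior: float | None) -> np.ndarray:
    if root_prior is None:
        pi1 = gain / (gain + loss) if gain + loss > 0 else 0.0
    else:
        pi1 = root_prior
    return np.array([1.0 - pi1, pi1])


def _category_loglik(
    codes: np.ndarray,
    tree: TreeIndex,
    loss: float,
    gain: float,
    root_prior: float | None = None,
) -> tuple[np.ndarray, float]:
    """Per-site likelihoods and P(all leaves absent) for one loss category."""
    n_sites = codes.shape[0]
    prior = _root_prior(loss, gain, root_prior)
    col_of_leaf = {int(leaf): j for j, leaf in enumerate(tree.leaf_indices)}

    partial: dict[int, np.ndarray] = {}
    absent_partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for node in tree.postorder:
        if tree.is_leaf[node]:
            states = codes[:, col_of_leaf[node]]
            p = np.ones((n_sites, 2))
            p[states == 1, 0] = 0.0
            p[states == 0, 1] = 0.0
            partial[node] = p
            absent_partial[node] = np.array([1.0, 0.0])
        else:
            p = np.ones((n_sites, 2))
            q = np.ones(2)
            for c in tree.children[node]:
                M = _transition(loss, gain, tree.blen[c])
                p *= partial[c] @ M.T
                q *= M @ absent_partial[c]
                del partial[c]
            mx = p.max(axis=1)
            mx[mx == 0] = 1.0
            log_scale += np.log(mx)
            partial[node] = p / mx[:, None]
            absent_partial[node] = q
    site_lik = (partial[tree.root] * prior).sum(axis=1)
    p_unobservable = float(absent_partial[tree.root] @ prior)
    return np.log(site_lik) + log_scale, p_unobservable


def loglik(
    matrix: IntronSiteMatrix, tree: TreeIndex, model: RateModel
) -> float:
    """Observability-conditioned log-likelihood of the site matrix."""
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    codes = _matrix_codes(matrix, tree)
    return _loglik_codes(codes, tree, model)


def _loglik_codes(codes: np.ndarray, tree: TreeIndex, model: RateModel) -> float:
    site_log = []
    denom = 0.0
    for w, mult in zip(model.category_prior, model.loss_multipliers):
        lg, p_unobs = _category_loglik(
            codes, tree, model.loss_rate * mult, model.gain_rate, model.root_prior
        )
        site_log.append(np.log(w) + lg)
        denom += w * (1.0 - p_unobs)
    mix = np.logaddexp.reduce(np.stack(site_log), axis=0)
    if denom <= 0:
        return -np.inf
    return float(mix.sum() - codes.shape[0] * np.log(denom))


@dataclass
class FitResult:
    model: RateModel
    loglik: float
    converged: bool
    n_evaluations: int
    history: list[float] = field(default_factory=list)


def fit_rates(
    matrix: IntronSiteMatrix,
    tree: TreeIndex,
    kind: str = "constant",
    max_rounds: int = 1000,
    tol: float = 0.001,
    seed: int | None = None,
    root: str = "stationary",
) -> FitResult:
    """Maximum-likelihood global rates via bounded quasi-Newton multi-start.

    With ``root="free"`` the root presence probability (ancestral intron
    content) is optimized as an extra parameter instead of being pinned to
    the stationary distribution of the global rates.
    """
    if matrix.n_sites < 50:
        warnings.warn(
            f"only {matrix.n_sites} sites; rate estimates will be unstable",
            stacklevel=2,
        )
    if root not in ("stationary", "free"):
        raise ValueError("root must be 'stationary' or 'free'")
    codes = _matrix_codes(matrix, tree)
    lo, hi = np.log(RATE_FLOOR), np.log(RATE_CEIL)
    free_root = root == "free"

    def unpack(x: np.ndarray) -> RateModel:
        loss, gain = np.exp(x[0]), np.exp(x[1])
        rp = 1.0 / (1.0 + np.exp(-x[-1])) if free_root else None
        if kind == "rate_variation":
            m = 2.0 / (1.0 + np.exp(-x[2]))
            m = min(max(m, 1e-6), 2 - 1e-6)
            return RateModel.rate_variation(loss, gain, m, root_prior=rp)
        return RateModel(kind="constant", loss_rate=loss, gain_rate=gain, root_prior=rp)

    evals = {"n": 0}

    def nll(x: np.ndarray) -> float:
        evals["n"] += 1
        return -_loglik_codes(codes, tree, unpack(x))

    rng = np.random.default_rng(seed)
    starts = [np.log([0.5, 0.1]), np.log([1.0, 1.0])]
    starts.append(rng.uniform(np.log(0.01), np.log(5.0), size=2))
    bounds = [(lo, hi), (lo, hi)]
    if kind == "rate_variation":
        starts = [np.concatenate([s, [rng.normal(0.0, 0.5)]]) for s in starts]
        bounds.append((-12.0, 12.0))
    if free_root:
        starts = [np.concatenate([s, [0.0]]) for s in starts]
        bounds.append((-12.0, 12.0))

    best = None
    trace: list[float] = []
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_rounds, "ftol": tol * 1e-4},
        )
        trace.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if not converged:
        logger.warning("rate optimization did not report convergence")
    return FitResult(
        model=unpack(best.x),
        loglik=-float(best.fun),
        converged=converged,
        n_evaluations=evals["n"],
        history=trace,
    )


@dataclass(frozen=True)
class LRTResult:
    delta: float
    p_value: float
    underflow: bool = False


def lrt(L1: float, L2: float, df: int = 1) -> LRTResult:
    """Likelihood-ratio test of the constant model (L1) vs the richer one (L2).

    Delta = -2 (L1 - L2), compared to a chi-square with ``df`` degrees of
    freedom; p-values below 1e-300 are reported as 0 with the underflow flag.
    """
    delta = -2.0 * (L1 - L2)
    if delta < 0:
        warnings.warn(
            "negative LRT statistic: the richer model fit worse (optimizer failure?)",
            stacklevel=2,
        )
    p = float(stats.chi2.sf(delta, df))
    if 0 < p < 1e-300 or (p == 0.0 and delta > 0):
        return LRTResult(delta=delta, p_value=0.0, underflow=True)
    return LRTResult(delta=delta, p_value=p, underflow=False)


def _updown_posteriors(
    codes: np.ndarray,
    tree: TreeIndex,
    loss: float,
    gain: float,
    root_prior: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-branch loss/gain joint probabilities (unnormalized) for one category.

    Returns (loss_joint[sites, nodes], gain_joint[sites, nodes],
    site_lik[sites], node_present_joint[sites, nodes]).
    """
    n_sites = codes.shape[0]
    prior = _root_prior(loss, gain, root_prior)
    col_of_leaf = {int(leaf): j for j, leaf in enumerate(tree.leaf_indices)}

    U: dict[int, np.ndarray] = {}
    C: dict[int, np.ndarray] = {}
    M: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        if tree.is_leaf[node]:
            states = codes[:, col_of_leaf[node]]
            p = np.ones((n_sites, 2))
            p[states == 1, 0] = 0.0
            p[states == 0, 1] = 0.0
            U[node] = p
        else:
            p = np.ones((n_sites, 2))
            for c in tree.children[node]:
                p *= C[c]
            U[node] = p
        if node != tree.root:
            M[node] = _transition(loss, gain, tree.blen[node])
            C[node] = U[node] @ M[node].T

    O: dict[int, np.ndarray] = {tree.root: np.broadcast_to(prior, (n_sites, 2)).copy()}
    for node in tree.preorder():
        for v in tree.children[node]:
            sib = np.ones((n_sites, 2))
            for w in tree.children[node]:
                if w != v:
                    sib *= C[w]
            parent_side = O[node] * sib          # P(outside data, state(parent)=a)
            O[v] = parent_side @ M[v]
    site_lik = (U[tree.root] * prior).sum(axis=1)

    loss_joint = np.zeros((n_sites, tree.n_nodes))
    gain_joint = np.zeros((n_sites, tree.n_nodes))
    present_joint = np.zeros((n_sites, tree.n_nodes))
    present_joint[:, tree.root] = prior[1] * U[tree.root][:, 1]
    for node in tree.preorder():
        for v in tree.children[node]:
            sib = np.ones((n_sites, 2))
            for w in tree.children[node]:
                if w != v:
                    sib *= C[w]
            parent_side = O[node] * sib
            loss_joint[:, v] = parent_side[:, 1] * M[v][1, 0] * U[v][:, 0]
            gain_joint[:, v] = parent_side[:, 0] * M[v][0, 1] * U[v][:, 1]
            present_joint[:, v] = (parent_side @ M[v])[:, 1] * U[v][:, 1]
    return loss_joint, gain_joint, site_lik, present_joint


def posterior_events(
    matrix: IntronSiteMatrix,
    tree: TreeIndex,
    model: RateModel,
    threshold: float = 0.99,
) -> EventHistory:
    """Threshold per-branch event posteriors into an event history.

    Posteriors come from the up-down (inside-outside) pass under the fitted
    model, mixing over loss categories; ancestral node counts are the summed
    posterior presence probabilities.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    codes = _matrix_codes(matrix, tree)
    n_sites = codes.shape[0]
    loss_num = np.zeros((n_sites, tree.n_nodes))
    gain_num = np.zeros((n_sites, tree.n_nodes))
    pres_num = np.zeros((n_sites, tree.n_nodes))
    denom = np.zeros(n_sites)
    for w, mult in zip(model.category_prior, model.loss_multipliers):
        lj, gj, sl, pj = _updown_posteriors(
            codes, tree, model.loss_rate * mult, model.gain_rate, model.root_prior
        )
        loss_num += w * lj
        gain_num += w * gj
        pres_num += w * pj
        denom += w * sl
    loss_post = loss_num / denom[:, None]
    gain_post = gain_num / denom[:, None]
    pres_post = pres_num / denom[:, None]

    site_ids = list(matrix.table.index)
    branch_labels = [tree.labels[i] for i in range(tree.n_nodes)]
    site_losses: dict[str, list[str]] = {}
    site_gain: dict[str, str | None] = {}
    site_origin: dict[str, str | None] = {}
    branch_losses = {tree.labels[i]: 0 for i in range(tree.n_nodes) if i != tree.root}
    branch_gains = {tree.labels[i]: 0 for i in range(tree.n_nodes) if i != tree.root}
    rows = []
    eps = 1e-12
    for s, sid in enumerate(site_ids):
        losses = []
        gain_branch = None
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            lab = tree.labels[v]
            if loss_post[s, v] >= threshold - eps and loss_post[s, v] > 0:
                losses.append(lab)
                branch_losses[lab] += 1
                rows.append(
                    {"site_id": sid, "branch": lab, "event": "loss",
                     "posterior": float(loss_post[s, v])}
                )
            if gain_post[s, v] >= threshold - eps and gain_post[s, v] > 0:
                if gain_branch is None or gain_post[s, v] > gain_post[s, tree.index_of[gain_branch]]:
                    gain_branch = lab
                rows.append(
                    {"site_id": sid, "branch": lab, "event": "gain",
                     "posterior": float(gain_post[s, v])}
                )
        if gain_branch is not None:
            # one origin per site: only the best-supported gain is counted
            branch_gains[gain_branch] += 1
        site_losses[sid] = sorted(losses)
        site_gain[sid] = gain_branch
        site_origin[sid] = gain_branch if gain_branch is not None else (
            "root" if pres_post[s, tree.root] >= threshold - eps else None
        )
    node_counts = {
        branch_labels[v]: float(pres_post[:, v].sum()) for v in range(tree.n_nodes)
    }
    posterior_frame = pd.DataFrame(
        rows, columns=["site_id", "branch", "event", "posterior"]
    )
    return EventHistory(
        method="ml_posterior",
        site_origin=site_origin,
        site_losses=site_losses,
        site_gain=site_gain,
        branch_losses=branch_losses,
        branch_gains=branch_gains,
        node_counts=node_counts,
        event_posteriors=posterior_frame,
    )


def scaled_density(n_introns: float) -> float:
    """Scale an ancestral intron count to introns/kbp via the reference genome."""
    if n_introns < 0:
        raise ValueError("intron count must be >= 0")
    return n_introns * CELEGANS_DENSITY / CELEGANS_INTRON_COUNT


@dataclass
class BranchSummary:
    table: pd.DataFrame
    wilcoxon_statistic: float | None
    p_value: float | None
    note: str = ""


def branch_summary(history: EventHistory, tree: TreeIndex) -> BranchSummary:
    """Per-branch loss/gain table plus the paired loss-vs-gain signed-rank test."""
    rows = []
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        lab = tree.labels[v]
        losses = history.branch_losses.get(lab, 0)
        gains = history.branch_gains.get(lab, 0)
        t = tree.blen[v]
        rows.append(
            {
                "branch": lab,
                "losses": losses,
                "gains": gains,
                "branch_length": t,
                "loss_rate": losses / t,
                "gain_rate": gains / t,
            }
        )
    table = pd.DataFrame(rows).set_index("branch")
    diffs = (table["losses"] - table["gains"]).to_numpy()
    informative = np.count_nonzero(diffs)
    if informative < 3:
        return BranchSummary(
            table, None, None, note=f"only {informative} informative branches; test skipped"
        )
    stat, p = stats.wilcoxon(diffs, alternative="two-sided")
    return BranchSummary(table, float(stat), float(p))
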