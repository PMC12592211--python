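"""Ancestral V-SDR gene content under a two-state gain/loss birth-death
model.

Each orthogroup is coded present (1) when SDR-linked in a species and
absent (0) otherwise. Presence evolves along the dated species tree as a
two-state Markov chain with global gain rate g and loss rate l per unit
branch length, with among-family rate variation from a mean-one discretized
gamma (10 categories by default, one shared multiplier per family applied
to both rates). Likelihoods use Felsenstein pruning; marginal ancestral
posteriors use the standard up-down (inside-outside) pass, mixing gamma
categories by their per-family posterior weight. Gains and losses are
called from posterior state flips along branches, and each gained gene's
acquisition mechanism is read from orthologue locations outside the gained
clade (PAR -> SDR-boundary expansion, autosome -> translocation, absent
everywhere -> gene birth).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammainc

logger = logging.getLogger(__name__)

LOCATION_CODES = ("SDR", "PAR", "AUTOSOME", "ABSENT", "UNPLACED")

BOUNDARY_EXPANSION = "boundary_expansion"
TRANSLOCATION = "translocation"
BIRTH = "birth"
AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------------------
# Tree indexing

class TreeIndex:
    """Array view of a rooted dendropy tree: postorder node order, parents,
    branch lengths, and stable node labels (tips keep taxon labels; unnamed
    internal nodes get node<i>)."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        self.index_of = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(len(nodes), -1, dtype=int)
        self.blen = np.zeros(len(nodes))
        self.labels: list[str] = []
        n_internal = 0
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                self.parent[i] = self.index_of[id(node.parent_node)]
                self.blen[i] = node.edge.length or 0.0
                if self.blen[i] < 0:
                    raise ValueError("negative branch length")
            if node.is_leaf():
                self.labels.append(node.taxon.label)
            else:
                label = node.label
                if not label:
                    label = f"node{n_internal}"
                self.labels.append(label)
                n_internal += 1
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels are not unique")
        self.is_tip = np.array([n.is_leaf() for n in nodes])
        self.tip_index = {self.labels[i]: i
                          for i in range(len(nodes)) if self.is_tip[i]}
        self.children: list[list[int]] = [[] for _ in nodes]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.root = int(np.nonzero(self.parent == -1)[0][0])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def tips(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_tip[i]]

    def descendant_tips(self, node_label: str) -> list[str]:
        i = self.labels.index(node_label)
        out = []
        stack = [i]
        while stack:
            j = stack.pop()
            if self.is_tip[j]:
                out.append(self.labels[j])
            stack.extend(self.children[j])
        return out


# ---------------------------------------------------------------------------
# Model

@dataclass
class GainLossModel:
    gain: float
    loss: float
    gamma_shape: float | None = None
    n_categories: int = 10
    root_prior: str | tuple[float, float] = "stationary"

    def __post_init__(self) -> None:
        if self.gain < 0 or self.loss < 0:
            raise ValueError("rates must be >= 0")
        if self.gain + self.loss == 0:
            raise ValueError("g + l must be > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    def stationary(self) -> np.ndarray:
        pi1 = self.gain / (self.gain + self.loss)
        return np.array([1 - pi1, pi1])

    def root_distribution(self) -> np.ndarray:
        if self.root_prior == "stationary":
            return self.stationary()
        p = np.asarray(self.root_prior, dtype=float)
        if p.shape != (2,) or not math.isclose(p.sum(), 1.0):
            raise ValueError("root prior must be a length-2 distribution")
        return p

    def rate_multipliers(self) -> np.ndarray:
        if self.gamma_shape is None or self.n_categories == 1:
            return np.ones(1)
        return discretize_gamma(self.gamma_shape, self.n_categories)


def discretize_gamma(alpha: float, n_categories: int) -> np.ndarray:
    """Mean-one discretized gamma rate multipliers: equal-probability bins,
    each represented by its conditional mean (Yang 1994)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    edges = np.zeros(n_categories + 1)
    edges[-1] = np.inf
    from scipy.stats import gamma as gamma_dist

    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    edges[1:-1] = dist.ppf(np.arange(1, n_categories) / n_categories)
    # mean within each bin: alpha*scale * [P(a+1, b*alpha) - P(a+1, a_*alpha)]
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    means = (upper - lower) * n_categories
    return means / means.mean()


def transition_matrix(g: float, l: float, t: float,
                      warn: bool = True) -> np.ndarray:
    """2x2 transition probabilities of the gain/loss chain over time t.

    P01 = pi1 (1 - e^{-(g+l)t}) with pi1 = g/(g+l); rows sum to 1.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if g < 0 or l < 0:
        raise ValueError("rates must be >= 0")
    if g + l == 0:
        if warn:
            logger.warning("g = l = 0: identity transition matrix")
        return np.eye(2)
    pi1 = g / (g + l)
    decay = 1.0 - math.exp(-(g + l) * t)
    p01 = pi1 * decay
    p10 = (1 - pi1) * decay
    return np.array([[1 - p01, p01], [p10, 1 - p10]])


# ---------------------------------------------------------------------------
# Presence/absence coding

def encode_presence(locations: pd.DataFrame) -> pd.DataFrame:
    """Code an orthogroup x species location matrix into presence/absence:
    SDR -> 1; PAR/AUTOSOME/ABSENT/UNPLACED -> 0.

    A row with no SDR-linked species anywhere is all-zero (warned: such
    families carry no signal).
    """
    bad = set(np.unique(locations.values)) - set(LOCATION_CODES)
    if bad:
        raise ValueError(f"unknown location codes {sorted(bad)}")
    matrix = (locations == "SDR").astype(int)
    n_empty = int((matrix.sum(axis=1) == 0).sum())
    if n_empty:
        logger.warning("%d families have no SDR-linked species", n_empty)
    return matrix


# ---------------------------------------------------------------------------
# Likelihood machinery

def _tip_partials(index: TreeIndex, matrix: pd.DataFrame) -> np.ndarray:
    """Partial likelihoods at tips: shape (n_nodes, n_families, 2)."""
    tips = set(index.tips())
    cols = set(matrix.columns)
    if tips != cols:
        raise ValueError(
            f"matrix species {sorted(cols)} do not match tree tips "
            f"{sorted(tips)}"
        )
    n_fam = len(matrix)
    partials = np.ones((index.n_nodes, n_fam, 2))
    for tip, col in ((t, matrix[t].to_numpy()) for t in matrix.columns):
        i = index.tip_index[tip]
        partials[i, :, 0] = (col == 0).astype(float)
        partials[i, :, 1] = (col == 1).astype(float)
    return partials


def _pruning_up(index: TreeIndex, tip_partials: np.ndarray,
                g: float, l: float, rate: float) -> np.ndarray:
    """Inside (up) pass for one rate category: returns partials array."""
    partials = tip_partials.copy()
    pmats = [transition_matrix(g * rate, l * rate, index.blen[i], warn=False)
             for i in range(index.n_nodes)]
    for i in range(index.n_nodes):  # postorder
        if index.is_tip[i]:
            continue
        acc = np.ones_like(partials[i])
        for child in index.children[i]:
            acc *= partials[child] @ pmats[child].T
        partials[i] = acc
    return partials


def family_likelihoods(index: TreeIndex, matrix: pd.DataFrame,
                       model: GainLossModel) -> np.ndarray:
    """Per-family likelihood, averaged over gamma categories."""
    tp = _tip_partials(index, matrix)
    root_p = model.root_distribution()
    rates = model.rate_multipliers()
    liks = np.zeros((len(rates), len(matrix)))
    for c, rate in enumerate(rates):
        partials = _pruning_up(index, tp, model.gain, model.loss, rate)
        liks[c] = partials[index.root] @ root_p
    return liks.mean(axis=0)


def pattern_likelihood(tree: dendropy.Tree | TreeIndex,
                       pattern: dict[str, int],
                       model: GainLossModel) -> float:
    """Likelihood of one tip presence/absence pattern (Felsenstein pruning,
    gamma-mixed)."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    missing = set(index.tips()) - set(pattern)
    if missing:
        raise ValueError(f"pattern missing tips {sorted(missing)}")
    matrix = pd.DataFrame([pattern])[index.tips()]
    return float(family_likelihoods(index, matrix, model)[0])


def fit_gain_loss(tree: dendropy.Tree | TreeIndex, matrix: pd.DataFrame,
                  n_categories: int = 10, restarts: int = 10,
                  tol: float = 0.1, seed: int = 0,
                  root_prior: str | tuple[float, float] = "stationary",
                  fit_gamma: bool = True
                  ) -> tuple[GainLossModel, float]:
    """Maximum-likelihood gain/loss rates (and gamma shape) by multi-start
    quasi-Newton optimization on log parameters.

    ``restarts`` random restarts (seeded, deterministic); a restart round is
    accepted as converged when it improves the best log-likelihood by less
    than ``tol``.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if len(matrix) == 0:
        raise ValueError("empty presence/absence matrix")
    values = matrix.to_numpy()
    if (values == values.flat[0]).all():
        logger.warning("all-identical matrix: boundary rate estimate")
    rng = np.random.default_rng(seed)

    def objective(log_params: np.ndarray) -> float:
        g, l = np.exp(log_params[0]), np.exp(log_params[1])
        alpha = np.exp(log_params[2]) if fit_gamma else None
        try:
            model = GainLossModel(g, l, gamma_shape=alpha,
                                  n_categories=n_categories,
                                  root_prior=root_prior)
        except ValueError:
            return 1e12
        liks = family_likelihoods(index, matrix, model)
        if (liks <= 0).any():
            return 1e12
        return -float(np.log(liks).sum())

    n_params = 3 if fit_gamma else 2
    best: tuple[float, np.ndarray] | None = None
    starts = [np.zeros(n_params)]
    starts += [rng.uniform(-2, 1, size=n_params) for _ in range(restarts - 1)]
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=[(-12, 6)] * n_params)
        improvement = math.inf if best is None else best[0] - res.fun
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
        if improvement < tol and best is not None and x0 is not starts[0]:
            break
    assert best is not None
    g, l = float(np.exp(best[1][0])), float(np.exp(best[1][1]))
    alpha = float(np.exp(best[1][2])) if fit_gamma else None
    model = GainLossModel(g, l, gamma_shape=alpha,
                          n_categories=n_categories, root_prior=root_prior)
    return model, -best[0]


def ancestral_posteriors(tree: dendropy.Tree | TreeIndex,
                         matrix: pd.DataFrame,
                         model: GainLossModel) -> pd.DataFrame:
    """Marginal posterior P(present) per (family, node) by the up-down
    algorithm, mixed over gamma categories by their per-family posterior
    weights. Tip posteriors equal the observations."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    tp = _tip_partials(index, matrix)
    root_p = model.root_distribution()
    rates = model.rate_multipliers()
    n_fam = len(matrix)
    n_cat = len(rates)

    post = np.zeros((n_cat, index.n_nodes, n_fam))
    cat_lik = np.zeros((n_cat, n_fam))
    for c, rate in enumerate(rates):
        g, l = model.gain * rate, model.loss * rate
        up = _pruning_up(index, tp, model.gain, model.loss, rate)
        pmats = [transition_matrix(g, l, index.blen[i], warn=False)
                 for i in range(index.n_nodes)]
        down = np.zeros((index.n_nodes, n_fam, 2))
        down[index.root] = root_p
        for i in reversed(range(index.n_nodes)):  # preorder
            if index.is_tip[i]:
                continue
            for child in index.children[i]:
                msg = down[i].copy()
                for sibling in index.children[i]:
                    if sibling != child:
                        msg *= up[sibling] @ pmats[sibling].T
                down[child] = msg @ pmats[child]
        joint = up * down
        norm = joint.sum(axis=2)
        cat_lik[c] = (up[index.root] * root_p).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            post[c] = np.where(norm > 0, joint[:, :, 1] / norm, 0.0)
    weights = cat_lik / cat_lik.sum(axis=0, keepdims=True)
    mixed = (post * weights[:, None, :]).sum(axis=0)
    return pd.DataFrame(mixed.T, index=matrix.index, columns=index.labels)


def expected_gene_count(posteriors: pd.DataFrame) -> pd.Series:
    """Expected SDR gene count per node: sum of family posteriors."""
    return posteriors.sum(axis=0)


# ---------------------------------------------------------------------------
# Event calling and mechanism classification

def call_events(posteriors: pd.DataFrame, tree: dendropy.Tree | TreeIndex,
                threshold: float = 0.5) -> pd.DataFrame:
    """Call per-branch gains/losses from thresholded node states.

    State = 1 iff posterior >= threshold (ties present). A gain is a branch
    with parent 0 -> child 1, a loss the converse, retention 1 -> 1.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    states = (posteriors.to_numpy() >= threshold).astype(int)
    label_col = {lab: j for j, lab in enumerate(posteriors.columns)}
    rows = []
    for i in range(index.n_nodes):
        p = index.parent[i]
        if p < 0:
            continue
        child_lab, parent_lab = index.labels[i], index.labels[p]
        cs = states[:, label_col[child_lab]]
        ps_ = states[:, label_col[parent_lab]]
        for f, fam in enumerate(posteriors.index):
            if ps_[f] == 0 and cs[f] == 1:
                rows.append((fam, parent_lab, child_lab, "gain"))
            elif ps_[f] == 1 and cs[f] == 0:
                rows.append((fam, parent_lab, child_lab, "loss"))
            elif ps_[f] == 1 and cs[f] == 1:
                rows.append((fam, parent_lab, child_lab, "retention"))
    return pd.DataFrame(rows, columns=["family", "parent", "child", "event"])


def retention_counts(events: pd.DataFrame) -> pd.Series:
    """Number of families retained (1 -> 1) along the branch into each node."""
    sub = events[events["event"] == "retention"]
    return sub.groupby("child").size()


def classify_mechanism(family, branch_child: str,
                       locations: pd.DataFrame,
                       tree: dendropy.Tree | TreeIndex) -> str:
    """Acquisition mechanism of a gained family from orthologue locations in
    species outside the gained clade.

    Most frequent informative location: PAR -> boundary_expansion (SDR
    engulfed adjacent pseudoautosomal genes), AUTOSOME -> translocation,
    everything absent -> birth, PAR/autosome tie -> ambiguous. Outside
    species coded SDR (independently sex-linked) and UNPLACED are
    uninformative about the source location and do not vote.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    inside = set(index.descendant_tips(branch_child))
    outside = [t for t in index.tips() if t not in inside]
    if not outside:
        return AMBIGUOUS
    codes = [locations.at[family, sp] for sp in outside]
    n_par = sum(c == "PAR" for c in codes)
    n_auto = sum(c == "AUTOSOME" for c in codes)
    if n_par == 0 and n_auto == 0:
        return BIRTH
    if n_par > n_auto:
        return BOUNDARY_EXPANSION
    if n_auto > n_par:
        return TRANSLOCATION
    return AMBIGUOUS


def event_table(posteriors: pd.DataFrame, tree: dendropy.Tree | TreeIndex,
                locations: pd.DataFrame | None = None,
                threshold: float = 0.5) -> pd.DataFrame:
    """Events with acquisition mechanisms attached to gains."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    events = call_events(posteriors, index, threshold)
    mechanisms = []
    for rec in events.itertuples():
        if rec.event == "gain" and locations is not None:
            mechanisms.append(
                classify_mechanism(rec.family, rec.child, locations, index)
            )
        else:
            mechanisms.append(None)
    events["mechanism"] = mechanisms
    return events
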