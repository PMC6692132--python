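"""Presence/absence of mutations on a phylogeny via Fitch parsimony.

Input is a rooted tree (Newick; polytomies allowed) and binary tip states
per site (0 = ancestral base, 1 = mutant base).  Polytomies are resolved
randomly into an ensemble of strictly bifurcating trees; on each, two-pass
Fitch parsimony yields the minimum number of state transitions and a
most-parsimonious branch attribution.  Per-site summaries (mean transition
count, ancestral-state frequencies) feed a binomial regression of presence
on log fitness.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "load_tree",
    "resolve_polytomies",
    "fitch_ancestral",
    "count_events",
    "site_summary",
    "SiteEventSummary",
    "PresenceAnalysis",
    "PresenceFitnessModel",
    "PresenceFitnessResults",
    "presence_model",
]

# Fitch state sets as bitmasks: 1 -> {0}, 2 -> {1}, 3 -> {0,1}
_SET0, _SET1, _BOTH = 1, 2, 3


def load_tree(source: str, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted Newick tree; tip labels must be unique."""
    kwargs = {"path": source} if is_path else {"data": source}
    tree = dendropy.Tree.get(schema="newick", rooting="force-rooted", **kwargs)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tip names are not unique")
    if len(labels) < 4:
        raise ValueError("need >= 4 tips")
    return tree


def is_bifurcating(tree: dendropy.Tree) -> bool:
    return all(len(nd.child_nodes()) in (0, 2)
               for nd in tree.preorder_node_iter())


def resolve_polytomies(tree: dendropy.Tree, n_resolutions: int = 100,
                       seed: int | None = 0) -> list[dendropy.Tree]:
    """Ensemble of strictly bifurcating trees from random polytomy resolution.

    Each polytomy is resolved independently by sequential random pairing of
    its children; topology outside polytomies is untouched.  Deterministic
    under ``seed``.
    """
    rng = _random.Random(seed)
    out = []
    for _ in range(n_resolutions):
        t = tree.clone(depth=1)
        t.resolve_polytomies(rng=rng)
        out.append(t)
    return out


def _tip_mask(label: str, states: Mapping[str, int], missing: list[str]) -> int:
    if label not in states or states[label] is None:
        missing.append(label)
        return _BOTH
    s = int(states[label])
    if s not in (0, 1):
        raise ValueError(f"state for tip {label!r} must be 0 or 1, got {s}")
    return _SET0 if s == 0 else _SET1


def fitch_ancestral(tree: dendropy.Tree, states: Mapping[str, int]):
    """Bottom-up Fitch pass on a strictly bifurcating rooted tree.

    Returns ``(score, node_sets)`` where ``node_sets`` maps each node to its
    preliminary state set (bitmask: 1={0}, 2={1}, 3={0,1}).  Tips absent
    from ``states`` are treated as ambiguous {0,1} and logged via a warning.
    """
    if not is_bifurcating(tree):
        raise ValueError("tree must be strictly bifurcating; resolve polytomies first")
    node_sets: dict[dendropy.Node, int] = {}
    score = 0
    missing: list[str] = []
    for nd in tree.postorder_node_iter():
        kids = nd.child_nodes()
        if not kids:
            node_sets[nd] = _tip_mask(nd.taxon.label, states, missing)
            continue
        a, b = (node_sets[k] for k in kids)
        inter = a & b
        if inter:
            node_sets[nd] = inter
        else:
            node_sets[nd] = a | b
            score += 1
    if missing:
        warnings.warn(f"{len(missing)} tips without states treated as ambiguous: "
                      f"{missing[:5]}...")
    return score, node_sets


def count_events(tree: dendropy.Tree, node_sets: Mapping[dendropy.Node, int],
                 root_preference: int = 0):
    """Top-down resolution to one most-parsimonious reconstruction.

    Each node inherits its parent's resolved state when that state lies in
    the node's Fitch set, otherwise takes its own set's (unique) state; an
    ambiguous root resolves to ``root_preference`` (default the ancestral
    state 0).  This delayed-transformation choice guarantees the branch
    transition total equals the Fitch score.  Returns
    ``(total, branch_events, node_states)`` with ``branch_events`` mapping
    child nodes to 0/1 transitions on the branch above them.
    """
    node_states: dict[dendropy.Node, int] = {}
    branch_events: dict[dendropy.Node, int] = {}
    total = 0
    for nd in tree.preorder_node_iter():
        mask = node_sets[nd]
        if nd.parent_node is None:
            if mask == _BOTH:
                state = root_preference
            else:
                state = 0 if mask == _SET0 else 1
        else:
            parent = node_states[nd.parent_node]
            pmask = _SET0 if parent == 0 else _SET1
            if mask & pmask:
                state = parent
            else:
                state = 0 if mask == _SET0 else 1
            ev = int(state != parent)
            branch_events[nd] = ev
            total += ev
        node_states[nd] = state
    return total, branch_events, node_states


@dataclass(frozen=True)
class SiteEventSummary:
    """Per-site parsimony summary across the resolution ensemble."""

    site: str
    n_tips_mutant: int
    mean_events: float
    min_events: int
    max_events: int
    events: tuple[int, ...]
    presence_tip: int       # mutant observed on >= 1 tip
    presence_origin: int    # ...and with >= 1 inferred independent origin
    node_state_freq: Mapping[frozenset, float] = field(default_factory=dict)


def site_summary(tree: dendropy.Tree, states: Mapping[str, int],
                 n_resolutions: int = 100, seed: int | None = 0,
                 site: str = "site") -> SiteEventSummary:
    """Summarise one site over randomly resolved trees (convenience path)."""
    analysis = PresenceAnalysis(tree, pd.DataFrame(
        [{"site": site, "tip": k, "state": v} for k, v in states.items()]),
        n_resolutions=n_resolutions, seed=seed)
    return analysis.summaries()[site]


class PresenceAnalysis:
    """Site-by-site parsimony analysis over one shared resolution ensemble.

    ``tip_states`` is a long table (site, tip, state).  All sites are scored
    on the same ``n_resolutions`` randomly resolved bifurcating trees so
    that between-site comparisons are not confounded by different
    resolutions.  Internal nodes of the *input* tree are tracked across
    resolutions by their descendant-leaf sets; the frequency of inferred
    mutant ancestral state is reported per node.
    """

    def __init__(self, tree: dendropy.Tree, tip_states: pd.DataFrame,
                 n_resolutions: int = 100, seed: int | None = 0):
        req = {"site", "tip", "state"}
        if not req <= set(tip_states.columns):
            raise ValueError(f"tip_states missing columns: {sorted(req - set(tip_states.columns))}")
        self.tree = tree
        self.n_resolutions = n_resolutions
        self.seed = seed
        self.states = {
            str(site): dict(zip(grp["tip"].astype(str), grp["state"].astype(int)))
            for site, grp in tip_states.groupby("site")}
        self.tip_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        self.resolutions = resolve_polytomies(tree, n_resolutions, seed=seed)
        self._input_leafsets = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in tree.preorder_internal_node_iter()}
        # flatten each resolution once: postorder arrays + tracked leaf sets
        self._flat = [self._flatten(t) for t in self.resolutions]

    def _flatten(self, t: dendropy.Tree):
        """Postorder arrays: for each node its two child indices (or the tip
        label), plus internal nodes matching an input-tree leaf set."""
        nodes = list(t.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[tuple[int, int] | None] = []
        tips: list[str | None] = []
        leafsets: dict[int, frozenset] = {}
        cache: dict[int, frozenset] = {}
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            if not kids:
                children.append(None)
                tips.append(nd.taxon.label)
                cache[i] = frozenset([nd.taxon.label])
            else:
                ci = tuple(index[id(k)] for k in kids)
                children.append(ci)  # strictly bifurcating after resolution
                tips.append(None)
                ls = frozenset().union(*(cache[c] for c in ci))
                cache[i] = ls
                if ls in self._input_leafsets:
                    leafsets[i] = ls
        return children, tips, leafsets

    def _site_pass(self, flat, st: Mapping[str, int]):
        """Fitch bottom-up + delayed top-down on one flattened resolution."""
        children, tips, leafsets = flat
        n = len(children)
        sets = [0] * n
        score = 0
        for i in range(n):
            ci = children[i]
            if ci is None:
                s = st.get(tips[i])
                sets[i] = _BOTH if s is None else (_SET1 if int(s) else _SET0)
            else:
                a, b = sets[ci[0]], sets[ci[1]]
                inter = a & b
                if inter:
                    sets[i] = inter
                else:
                    sets[i] = a | b
                    score += 1
        # top-down (root is last in postorder)
        states = [0] * n
        root = n - 1
        m = sets[root]
        states[root] = 0 if m != _SET1 else 1
        for i in range(n - 1, -1, -1):
            ci = children[i]
            if ci is None:
                continue
            pstate = states[i]
            pmask = _SET0 if pstate == 0 else _SET1
            for c in ci:
                cm = sets[c]
                states[c] = pstate if (cm & pmask) else (0 if cm == _SET0 else 1)
        node_states = {leafsets[i]: states[i] for i in leafsets}
        return score, node_states

    def summaries(self) -> dict[str, SiteEventSummary]:
        out: dict[str, SiteEventSummary] = {}
        for site, st in self.states.items():
            events = []
            node_freq: dict[frozenset, float] = {ls: 0.0 for ls in self._input_leafsets}
            for flat in self._flat:
                score, node_states = self._site_pass(flat, st)
                events.append(score)
                for ls, s in node_states.items():
                    node_freq[ls] += s / self.n_resolutions
            n_mut = sum(1 for v in st.values() if int(v) == 1)
            mean_ev = float(np.mean(events))
            out[site] = SiteEventSummary(
                site=site, n_tips_mutant=n_mut, mean_events=mean_ev,
                min_events=int(min(events)), max_events=int(max(events)),
                events=tuple(events),
                presence_tip=int(n_mut >= 1),
                presence_origin=int(n_mut >= 1 and mean_ev >= 1.0),
                node_state_freq=node_freq)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"site": s.site, "n_tips_mutant": s.n_tips_mutant,
                 "mean_events": s.mean_events, "min_events": s.min_events,
                 "max_events": s.max_events, "presence_tip": s.presence_tip,
                 "presence_origin": s.presence_origin}
                for s in self.summaries().values()]
        return pd.DataFrame(rows).sort_values("site").reset_index(drop=True)


# ---------------------------------------------------------------------------
# presence ~ fitness model
# ---------------------------------------------------------------------------

@dataclass
class PresenceFitnessResults:
    """Binomial regression of phylogenetic presence on (log) fitness."""

    params: np.ndarray
    bse: np.ndarray
    slope: float
    p_lrt: float
    p_perm: float | None
    n_obs: int
    predictor: str
    presence_rule: str
    penalized: bool
    separation: bool
    B: int | None
    seed: int | None

    def summary(self) -> str:
        return (
            f"Presence ~ {self.predictor} (binomial GLM, logit link)\n"
            f"  presence rule   {self.presence_rule}\n"
            f"  n               {self.n_obs}\n"
            f"  slope           {self.slope:.4g} (se {self.bse[1]:.4g})\n"
            f"  LRT p           {self.p_lrt:.4g}\n"
            f"  permutation p   {self.p_perm if self.p_perm is not None else '-'}\n"
            + (f"  NOTE: complete separation; penalized fit used\n" if self.penalized else ""))


class PresenceFitnessModel:
    """Does the probability a mutation is seen across the phylogeny grow
    with its fitness?

    Fits ``presence ~ log(w)`` by binomial GLM (a linear-in-w variant via
    ``log_w=False``); inference by likelihood-ratio test against the
    intercept-only model, plus an optional label-permutation p-value.
    Complete separation is detected and reported, with an L2-penalized
    fallback fit.
    """

    def __init__(self, presence, w, log_w: bool = True,
                 presence_rule: str = "origin"):
        presence = np.asarray(presence, dtype=float)
        w = np.asarray(w, dtype=float)
        mask = np.isfinite(presence) & np.isfinite(w) & (w > 0)
        presence, w = presence[mask], w[mask]
        if presence.size < 10:
            raise ValueError(f"need >= 10 mutations, have {presence.size}")
        if len(set(presence)) < 2:
            raise ValueError("presence is constant; both outcome classes required")
        self.y = presence
        self.xname = "log(w)" if log_w else "w"
        self.x = np.log(w) if log_w else w
        self.presence_rule = presence_rule

    @staticmethod
    def _fit_glm(y: np.ndarray, X: np.ndarray):
        import statsmodels.api as sm

        return sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)

    def fit(self, B: int | None = 999, seed: int | None = 0) -> PresenceFitnessResults:
        import statsmodels.api as sm
        from scipy import stats as sps

        y, x = self.y, self.x
        X = np.column_stack([np.ones_like(x), x])
        penalized = separation = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = self._fit_glm(y, X)
                if np.any(np.abs(res.params) > 50) or not np.all(np.isfinite(res.bse)):
                    separation = True
            except Exception:
                separation = True
                res = None
        if separation:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                logit = sm.Logit(y, X)
                res = logit.fit_regularized(alpha=1.0, disp=0)
            penalized = True
            bse = np.full(2, np.nan)
            llf = logit.loglike(res.params)
        else:
            bse = np.asarray(res.bse)
            llf = res.llf
        null = self._fit_glm(y, np.ones((len(y), 1)))
        lr = max(2.0 * (llf - null.llf), 0.0)
        p_lrt = float(sps.chi2.sf(lr, df=1))

        p_perm = None
        if B:
            rng = np.random.default_rng(seed)
            exceed = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for _ in range(B):
                    yp = rng.permutation(y)
                    try:
                        rp = self._fit_glm(yp, X)
                        lr_p = 2.0 * (rp.llf - self._fit_glm(yp, np.ones((len(y), 1))).llf)
                    except Exception:
                        lr_p = np.inf   # count failures conservatively
                    if lr_p >= lr - 1e-9:
                        exceed += 1
            p_perm = (1 + exceed) / (B + 1)
        return PresenceFitnessResults(
            params=np.asarray(res.params), bse=bse,
            slope=float(np.asarray(res.params)[1]), p_lrt=p_lrt,
            p_perm=p_perm, n_obs=len(y), predictor=self.xname,
            presence_rule=self.presence_rule, penalized=penalized,
            separation=separation, B=B, seed=seed)


def presence_model(presence_df: pd.DataFrame, fitness_df: pd.DataFrame,
                   rule: str = "origin", log_w: bool = True,
                   B: int | None = 999, seed: int | None = 0) -> PresenceFitnessResults:
    """Join per-site presence with per-mutation fitness and fit the GLM.

    ``rule`` selects the presence definition: ``"origin"`` (mutant on >= 1
    tip and mean inferred origins >= 1, the relatedness-aware rule) or
    ``"tip"`` (raw tip occurrence).
    """
    col = {"origin": "presence_origin", "tip": "presence_tip"}[rule]
    df = presence_df.rename(columns={"site": "mutation_id"}).merge(
        fitness_df, on="mutation_id", how="inner")
    model = PresenceFitnessModel(df[col].to_numpy(), df["w_mean"].to_numpy(),
                                 log_w=log_w, presence_rule=rule)
    return model.fit(B=B, seed=seed)
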