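"""Phylogenetic and species-level signal in trends and fluctuations.

Within a taxonomic class, per-series responses are modelled with an
intercept-only Gaussian mixed model carrying two species-level random
effects: one whose covariance follows the phylogeny (Brownian-motion shared
branch lengths, scaled to a correlation matrix) and one iid, plus a
residual.  The posterior distributions of the three variance components say
whether closely related species — or species identity itself — explain
variation: a posterior pushed up against zero indicates lack of effect.

Phylogenetic uncertainty is handled by refitting the identical model over a
set of trees (10 by default, sampled from a larger pool) and reporting the
across-tree mean and range of each component.

The sampler uses parameter expansion: each random-effect block u is written
as alpha * w with alpha ~ N(0, 1) and w ~ N(0, eta^2 * C),
eta^2 ~ inverse-gamma(nu/2, nu*V/2) (V=1, nu=1 by default), which implies a
heavy-tailed half-Cauchy-like prior on the block standard deviation and
mixes well when a variance is near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloCorrelation",
    "PhyloVarianceDecomposition",
    "PhylogeneticMixedModel",
    "read_newick_trees",
    "tree_to_correlation",
    "fit_phylo_mixed",
    "multi_tree_summary",
]


def normalize_tip_label(label: str) -> str:
    """Canonical binomial form: underscores to spaces, collapsed whitespace."""
    return " ".join(str(label).replace("_", " ").split())


@dataclass
class PhyloCorrelation:
    """Brownian-motion correlation among species implied by a tree.

    Entry (a, b) is the shared root-to-tip path length normalised by the
    root-to-tip depths (sqrt(d_a * d_b); equal to tree depth for ultrametric
    trees), so the diagonal is 1 and the matrix is positive semi-definite.
    """

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.matrix = m

    def index_of(self, species_names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species_names if s not in lookup]
        if missing:
            raise KeyError(f"species absent from correlation: {missing}")
        return np.array([lookup[s] for s in species_names])


def read_newick_trees(path, k: int = 10, seed: int | None = None) -> list[dendropy.Tree]:
    """Read a Newick file (one or many trees) and sample ``k`` of them
    without replacement, reproducibly given ``seed``.

    Tip labels are normalised (underscores become spaces) so they match
    binomial names.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    if k > len(trees):
        raise ValueError(f"requested {k} trees but file holds {len(trees)}")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(trees), size=k, replace=False))
    chosen = [trees[i] for i in idx]
    for t in chosen:
        for leaf in t.leaf_node_iter():
            if leaf.taxon is not None:
                leaf.taxon.label = normalize_tip_label(leaf.taxon.label)
    return chosen


def tree_to_correlation(tree: dendropy.Tree, species_subset=None) -> PhyloCorrelation:
    """Brownian-motion correlation matrix from shared branch lengths.

    Missing branch lengths count as zero.  Raises KeyError listing species
    in ``species_subset`` that are not tips of the tree.
    """
    # root-to-tip distances via a preorder sweep
    depth = {}
    tree_ = tree
    for node in tree_.preorder_node_iter():
        el = node.edge.length or 0.0
        depth[node] = (depth.get(node.parent_node, 0.0) + el) if node.parent_node else 0.0
    tips = {}
    for leaf in tree_.leaf_node_iter():
        if leaf.taxon is None:
            continue
        tips[normalize_tip_label(leaf.taxon.label)] = leaf
    if species_subset is None:
        species = sorted(tips)
    else:
        species = [normalize_tip_label(s) for s in species_subset]
        missing = [s for s in species if s not in tips]
        if missing:
            raise KeyError(f"species not found as tips: {missing}")
    # ancestor chains with cumulative depths
    chains = {}
    for s in species:
        chain = []
        node = tips[s]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains[s] = set(chain)
    n = len(species)
    shared = np.zeros((n, n))
    d = np.array([depth[tips[s]] for s in species])
    for i in range(n):
        shared[i, i] = d[i]
        for j in range(i + 1, n):
            common = chains[species[i]] & chains[species[j]]
            mrca_depth = max(depth[node] for node in common)
            shared[i, j] = shared[j, i] = mrca_depth
    scale = np.sqrt(np.maximum(d, 1e-300))
    corr = shared / np.outer(scale, scale)
    np.fill_diagonal(corr, 1.0)
    return PhyloCorrelation(species, corr)


@dataclass
class PhyloTreeResults:
    """Posterior draws of the variance components for one tree."""

    draws: dict[str, np.ndarray]
    n_species: int
    n_obs: int

    COMPONENTS = ("var_phylo", "var_species", "var_residual")

    def component_summary(self, level: float = 0.95) -> pd.DataFrame:
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        rows = []
        for c in self.COMPONENTS:
            d = self.draws[c]
            lo, hi = np.quantile(d, [lo_q, hi_q])
            rows.append(dict(component=c, mean=float(np.mean(d)),
                             ci_lo=float(lo), ci_hi=float(hi)))
        return pd.DataFrame(rows).set_index("component")

    def shares(self) -> dict[str, np.ndarray]:
        total = sum(self.draws[c] for c in self.COMPONENTS)
        return {c: self.draws[c] / total for c in self.COMPONENTS}


@dataclass
class PhyloVarianceDecomposition:
    """Across-tree summary of the variance decomposition.

    ``pushed_against_zero`` marks components whose posterior concentrates
    near zero (operationalised: the 15th percentile of the component's share
    of total variance falls below 5%; thresholds configurable).
    """

    component_means: dict[str, float]
    component_ranges: dict[str, tuple[float, float]]
    per_tree: list[PhyloTreeResults] = field(repr=False, default_factory=list)
    pushed_against_zero: dict[str, bool] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Phylogenetic variance decomposition "
                 f"({len(self.per_tree)} tree(s))"]
        for c, m in self.component_means.items():
            lo, hi = self.component_ranges[c]
            flag = "  [pushed against zero]" if self.pushed_against_zero.get(c) else ""
            lines.append(f"  {c:13s} mean {m: .6f}   range ({lo: .6f}, {hi: .6f}){flag}")
        return "\n".join(lines)


class PhylogeneticMixedModel:
    """Intercept-only Gaussian model with phylogenetically correlated and iid
    species random effects, fitted by parameter-expanded Gibbs sampling.

    Parameters
    ----------
    responses : array-like
        Per-series response (trend mu or a fluctuation metric).
    species : array-like of str
        Species of each series; must all appear in ``corr``.
    corr : PhyloCorrelation
        Among-species Brownian-motion correlation from one tree.
    """

    def __init__(self, responses, species, corr: PhyloCorrelation,
                 px_alpha_var: float = 1.0, iw_v: float = 1.0, iw_nu: float = 1.0,
                 beta_prior_var: float = 1e8):
        self.y = np.asarray(responses, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite responses")
        species = [normalize_tip_label(s) for s in np.asarray(species)]
        uniq = sorted(set(species))
        if len(uniq) < 2:
            raise ValueError("need >= 2 species")
        self.species_labels = uniq
        order = corr.index_of(uniq)
        self.C = corr.matrix[np.ix_(order, order)]
        lookup = {s: i for i, s in enumerate(uniq)}
        self.idx = np.array([lookup[s] for s in species])
        self.n_species = len(uniq)
        self.px_alpha_var = px_alpha_var
        # IG(nu/2, nu*V/2) per-block working-variance prior
        self.ig_a = iw_nu / 2.0
        self.ig_b = iw_nu * iw_v / 2.0
        self.beta_prior_var = beta_prior_var
        self._prep_corr()

    def _prep_corr(self, floor: float = 1e-8):
        """Stable inverse of the correlation: eigenvalues floored at
        ``floor`` (trees with near-zero internal branches produce numerically
        singular matrices; the floor acts as the usual diagonal jitter)."""
        evals, evecs = np.linalg.eigh(self.C)
        n_floored = int(np.sum(evals < floor))
        if n_floored:
            logger.info("correlation near-singular: %d eigenvalue(s) floored "
                        "at %.1e", n_floored, floor)
        evals = np.clip(evals, floor, None)
        self._Cinv = (evecs / evals) @ evecs.T

    def fit(self, iterations: int = 20_000, burnin: int = 4_000, thin: int = 10,
            seed: int | None = None) -> PhyloTreeResults:
        """Gibbs sample the three variance components; seed-reproducible.

        Defaults are test-scale; production runs use longer chains via the
        arguments.
        """
        rng = np.random.default_rng(seed)
        y, idx, q = self.y, self.idx, self.n_species
        n = y.size
        counts = np.bincount(idx, minlength=q).astype(float)
        Cinv = self._Cinv
        a0, b0 = self.ig_a, self.ig_b

        beta0 = float(np.mean(y))
        wu = np.zeros(q)
        wv = np.zeros(q)
        au = av = 0.5
        eta_u = eta_v = max(float(np.var(y)), 1e-6)
        var_e = max(float(np.var(y)), 1e-6)

        keep = (iterations - burnin) // thin
        out = {k: np.empty(keep) for k in
               ("var_phylo", "var_species", "var_residual", "intercept")}
        k = 0
        eye_q = np.eye(q)
        for it in range(iterations):
            zu = au * wu[idx]
            zv = av * wv[idx]
            # intercept
            prec0 = n / var_e + 1.0 / self.beta_prior_var
            m0 = np.sum(y - zu - zv) / var_e / prec0
            beta0 = m0 + rng.standard_normal() / np.sqrt(prec0)
            # phylo working effects (dense: correlated prior)
            r = y - beta0 - zv
            rs = np.bincount(idx, weights=r, minlength=q)
            prec_u = Cinv / eta_u + (au**2 / var_e) * np.diag(counts)
            try:
                Lu = np.linalg.cholesky(prec_u)
            except np.linalg.LinAlgError:
                ridge = 1e-10 * np.trace(prec_u) / q
                Lu = np.linalg.cholesky(prec_u + ridge * eye_q)
            mu_u = np.linalg.solve(Lu.T, np.linalg.solve(Lu, (au / var_e) * rs))
            wu = mu_u + np.linalg.solve(Lu.T, rng.standard_normal(q))
            # phylo expansion scalar
            g = wu[idx]
            prec_a = g @ g / var_e + 1.0 / self.px_alpha_var
            m_a = (g @ r / var_e) / prec_a
            au = m_a + rng.standard_normal() / np.sqrt(prec_a)
            zu = au * wu[idx]
            # phylo working variance
            quad = wu @ Cinv @ wu
            eta_u = 1.0 / rng.gamma(a0 + q / 2.0, 1.0 / (b0 + 0.5 * quad))
            # iid species working effects (diagonal prior)
            r = y - beta0 - zu
            rs = np.bincount(idx, weights=r, minlength=q)
            prec_v = 1.0 / eta_v + (av**2 / var_e) * counts
            m_v = (av / var_e) * rs / prec_v
            wv = m_v + rng.standard_normal(q) / np.sqrt(prec_v)
            g = wv[idx]
            prec_a = g @ g / var_e + 1.0 / self.px_alpha_var
            m_a = (g @ r / var_e) / prec_a
            av = m_a + rng.standard_normal() / np.sqrt(prec_a)
            zv = av * wv[idx]
            eta_v = 1.0 / rng.gamma(a0 + q / 2.0, 1.0 / (b0 + 0.5 * wv @ wv))
            # residual
            resid = y - beta0 - zu - zv
            var_e = 1.0 / rng.gamma(a0 + n / 2.0,
                                    1.0 / (b0 + 0.5 * resid @ resid))
            if it >= burnin and (it - burnin) % thin == 0:
                out["var_phylo"][k] = au**2 * eta_u
                out["var_species"][k] = av**2 * eta_v
                out["var_residual"][k] = var_e
                out["intercept"][k] = beta0
                k += 1
        return PhyloTreeResults(out, q, n)


def fit_phylo_mixed(responses, species, corr: PhyloCorrelation,
                    iterations: int = 20_000, burnin: int = 4_000,
                    thin: int = 10, seed: int | None = None,
                    **model_kw) -> PhyloTreeResults:
    """Fit the two-random-effect phylogenetic model for one tree."""
    model = PhylogeneticMixedModel(responses, species, corr, **model_kw)
    return model.fit(iterations=iterations, burnin=burnin, thin=thin, seed=seed)


def multi_tree_summary(decomps: list[PhyloTreeResults],
                       zero_mass_quantile: float = 0.15,
                       zero_share_threshold: float = 0.05) -> PhyloVarianceDecomposition:
    """Across-tree mean and (min, max) range per variance component, with
    the pushed-against-zero assessment pooled over trees."""
    if not decomps:
        raise ValueError("need at least one per-tree result")
    means, ranges, pushed = {}, {}, {}
    for c in PhyloTreeResults.COMPONENTS:
        per_tree_means = [float(np.mean(d.draws[c])) for d in decomps]
        means[c] = float(np.mean(per_tree_means))
        ranges[c] = (float(np.min(per_tree_means)), float(np.max(per_tree_means)))
        share_q = [float(np.quantile(d.shares()[c], zero_mass_quantile))
                   for d in decomps]
        pushed[c] = bool(np.mean(share_q) < zero_share_threshold)
    return PhyloVarianceDecomposition(means, ranges, list(decomps), pushed)
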