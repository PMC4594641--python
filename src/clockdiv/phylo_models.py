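"""Empirical amino-acid substitution models and likelihood machinery.

A model couples a symmetric 20x20 exchangeability matrix s with equilibrium
frequencies pi, optionally extended by +G (discrete-gamma rate
heterogeneity, k equal-weight categories), +I (a proportion of invariant
sites) and +F (frequencies taken from the alignment, with one pseudo-count
per residue).  The generator Q(i,j) = s(i,j) pi(j) is normalised to one
expected substitution per unit branch length at equilibrium, so branch
lengths are in substitutions per site.

Log-likelihoods are computed with Felsenstein's pruning algorithm; gaps and
'X' are treated as missing data.  Model selection ranks candidates by AIC
with alpha and p_inv optimised per candidate by bounded search, which is
the standard sequence of decisions behind best-fit amino-acid model choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, gammaincinv

from .io_formats import Msa

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # PAML convention
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
MISSING = set("-X*BZJUO")

_MATRIX_FILES = {"JTT": "jtt.dat", "LG": "lg.dat", "Dayhoff": "dayhoff.dat", "WAG": "wag.dat"}
_MATRIX_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def load_empirical(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Load (exchangeabilities, frequencies) for JTT/LG/Dayhoff/WAG from the
    packaged PAML-format .dat files (lower triangle, then 20 frequencies)."""
    if name in _MATRIX_CACHE:
        s, pi = _MATRIX_CACHE[name]
        return s.copy(), pi.copy()
    if name not in _MATRIX_FILES:
        raise ValueError(f"unknown empirical model {name!r}; have {sorted(_MATRIX_FILES)}")
    text = resources.files("clockdiv.data").joinpath(_MATRIX_FILES[name]).read_text()
    values = [float(x) for x in text.split()]
    if len(values) < 210:
        raise ValueError(f"matrix file for {name} is truncated")
    tri, pi = values[:190], np.array(values[190:210])
    s = np.zeros((20, 20))
    it = iter(tri)
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = next(it)
    pi = pi / pi.sum()
    _MATRIX_CACHE[name] = (s.copy(), pi.copy())
    return s, pi


@dataclass(frozen=True)
class SubstitutionModel:
    """An (optionally extended) empirical replacement model.

    ``alpha``/``p_inv`` being ``None`` means the extension is off;
    ``plus_F`` marks that ``frequencies`` came from the data.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    n_categories: int = 4
    p_inv: float | None = None
    plus_F: bool = False

    def __post_init__(self) -> None:
        s, pi = self.exchangeabilities, self.frequencies
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be symmetric 20x20")
        if np.any(np.diag(s) != 0):
            raise ValueError("exchangeability diagonal must be zero")
        if abs(pi.sum() - 1) > 1e-12 or np.any(pi <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.p_inv is not None and not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")

    @property
    def n_free_params(self) -> int:
        k = 0
        if self.alpha is not None:
            k += 1
        if self.p_inv is not None:
            k += 1
        if self.plus_F:
            k += 19
        return k

    def with_observed_frequencies(self, msa: Msa) -> "SubstitutionModel":
        pi = observed_frequencies(msa)
        return replace(self, frequencies=pi, plus_F=True)


def base_model(name: str) -> SubstitutionModel:
    s, pi = load_empirical(name)
    return SubstitutionModel(name=name, exchangeabilities=s, frequencies=pi)


def poisson_model() -> SubstitutionModel:
    """Equal exchangeabilities, uniform frequencies (the aa Jukes-Cantor)."""
    s = np.ones((20, 20)) - np.eye(20)
    pi = np.full(20, 1 / 20)
    return SubstitutionModel(name="Poisson", exchangeabilities=s, frequencies=pi)


def observed_frequencies(msa: Msa, pseudocount: float = 1.0) -> np.ndarray:
    counts = np.full(20, pseudocount)
    for rec in msa.records:
        for c in rec.residues.upper():
            idx = AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Generator Q with rows summing to zero, normalised to mean rate 1."""
    pi = model.frequencies
    if np.any(pi <= 0):
        raise ValueError("zero equilibrium frequency; smoothing failed")
    Q = model.exchangeabilities * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


@dataclass
class _Propagator:
    """Eigendecomposition of Q for fast P(t) = exp(Qt).

    Q is similar to the symmetric B = D^{1/2} Q D^{-1/2} (D = diag(pi)),
    so P(t) = D^{-1/2} U exp(L t) U' D^{1/2} with B = U L U'.
    """

    eigvals: np.ndarray
    left: np.ndarray   # D^{-1/2} U
    right: np.ndarray  # U' D^{1/2}

    @classmethod
    def from_model(cls, model: SubstitutionModel) -> "_Propagator":
        Q = build_rate_matrix(model)
        pi = model.frequencies
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        B = (B + B.T) / 2
        lam, U = np.linalg.eigh(B)
        return cls(lam, U / sq[:, None], (U * sq[:, None]).T)

    def probs(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.eigvals * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probs(model: SubstitutionModel, t: float) -> np.ndarray:
    """Stochastic matrix exp(Qt); rows sum to 1, negative round-off clamped."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    return _Propagator.from_model(model).probs(t)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-bin discretisation of Gamma(alpha, mean 1) into k
    equal-probability categories, renormalised to mean exactly 1."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    cuts = gammaincinv(alpha, probs) / alpha  # quantiles of mean-1 gamma
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X; a<X<b] for Gamma(alpha, scale 1/alpha) = I(alpha+1, alpha*b) - I(alpha+1, alpha*a)
    upper = gammainc(alpha + 1, np.where(np.isinf(bounds[1:]), np.inf, alpha * bounds[1:]))
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class LikelihoodResult:
    loglik: float
    per_site: np.ndarray
    n_free_params: int


def encode_alignment(msa: Msa) -> np.ndarray:
    """Integer codes per (row, column); -1 marks missing (gap/'X')."""
    out = np.full((len(msa.records), msa.n_cols), -1, dtype=np.int64)
    for i, rec in enumerate(msa.records):
        for j, c in enumerate(rec.residues.upper()):
            out[i, j] = AA_INDEX.get(c, -1)
    return out


def _postorder(tree: dendropy.Tree):
    nodes = list(tree.seed_node.postorder_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    return nodes, index


def prune_loglik(tree: dendropy.Tree, msa: Msa, model: SubstitutionModel) -> LikelihoodResult:
    """Felsenstein pruning log-likelihood of the alignment on the tree.

    Per-site likelihood combines the invariant-site component (when +I) with
    the average over gamma categories (when +G):

        L_s = p_inv * [site constant] * pi(residue)
            + (1 - p_inv) * (1/k) * sum_c L_pruning(rate_c * branch lengths)

    Gaps/'X' are missing data (partial vectors of ones at the leaf).
    """
    leaf_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if sorted(msa.ids) != leaf_labels:
        only_tree = sorted(set(leaf_labels) - set(msa.ids))
        only_msa = sorted(set(msa.ids) - set(leaf_labels))
        raise ValueError(
            f"tree/alignment id mismatch; only in tree: {only_tree}, only in alignment: {only_msa}"
        )
    codes = encode_alignment(msa)
    row_of = {sid: i for i, sid in enumerate(msa.ids)}
    pi = model.frequencies
    prop = _Propagator.from_model(model)
    p_inv = model.p_inv or 0.0
    if model.alpha is not None:
        rates = discrete_gamma_rates(model.alpha, model.n_categories)
    else:
        rates = np.ones(1)

    nodes, _ = _postorder(tree)
    n_sites = msa.n_cols

    site_lik = np.zeros(n_sites)
    for rate in rates:
        partials: dict[int, np.ndarray] = {}
        for node in nodes:
            if node.is_leaf():
                code_row = codes[row_of[node.taxon.label]]
                part = np.ones((n_sites, 20))
                observed = code_row >= 0
                part[observed] = 0.0
                part[observed, code_row[observed]] = 1.0
            else:
                part = np.ones((n_sites, 20))
                for child in node.child_nodes():
                    t = (child.edge.length or 0.0) * rate
                    P = prop.probs(t)
                    part *= partials.pop(id(child)) @ P.T
            partials[id(node)] = part
        root_part = partials[id(nodes[-1])]
        site_lik += (root_part @ pi) / len(rates)

    if p_inv > 0:
        inv = _invariant_site_likelihood(codes, pi)
        site_lik = p_inv * inv + (1 - p_inv) * site_lik
    per_site = np.log(np.maximum(site_lik, 1e-300))
    return LikelihoodResult(float(per_site.sum()), per_site, model.n_free_params)


def _invariant_site_likelihood(codes: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """pi(residue) for columns whose observed residues are all identical
    (1 for all-missing columns), else 0."""
    n_sites = codes.shape[1]
    out = np.zeros(n_sites)
    for j in range(n_sites):
        col = codes[:, j]
        obs = col[col >= 0]
        if obs.size == 0:
            out[j] = 1.0
        elif np.all(obs == obs[0]):
            out[j] = pi[obs[0]]
    return out


# ---------------------------------------------------------------------------
# Model selection


def candidate_grid(
    bases: Sequence[str] = ("JTT", "LG", "Dayhoff", "WAG"),
    extensions: Sequence[str] = ("", "+G", "+I+G", "+F", "+G+F", "+I+G+F"),
) -> list[str]:
    return [b + e for b in bases for e in extensions]


def model_from_name(name: str, msa: Msa | None = None) -> SubstitutionModel:
    """Instantiate e.g. 'LG+I+G+F'; +F requires the alignment."""
    parts = name.split("+")
    base = parts[0]
    model = poisson_model() if base == "Poisson" else base_model(base)
    flags = set(parts[1:])
    unknown = flags - {"G", "I", "F"}
    if unknown:
        raise ValueError(f"unknown model extensions {sorted(unknown)} in {name!r}")
    if "F" in flags:
        if msa is None:
            raise ValueError("+F needs an alignment for observed frequencies")
        model = model.with_observed_frequencies(msa)
    alpha = 1.0 if "G" in flags else None
    p_inv = 0.0 if "I" in flags else None
    return replace(model, name=name, alpha=alpha, p_inv=p_inv)


def _optimize_rate_params(tree, msa, model: SubstitutionModel) -> tuple[SubstitutionModel, float]:
    """Optimise alpha (if +G) and p_inv (if +I) by bounded search."""
    has_g = model.alpha is not None
    has_i = model.p_inv is not None

    def loglik_at(alpha, p_inv):
        m = replace(model, alpha=alpha, p_inv=p_inv)
        return prune_loglik(tree, msa, m).loglik

    if has_g and has_i:
        # start from the nested +G optimum (p_inv = 0) and keep the best
        # visited point, so the richer model never scores below the nested one
        res = minimize_scalar(
            lambda a: -loglik_at(np.exp(a), 0.0), bounds=(np.log(0.02), np.log(50.0)),
            method="bounded", options={"xatol": 1e-3})
        alpha = float(np.exp(res.x))
        best_ll = float(-res.fun)
        best_pair = (alpha, 0.0)
        p_inv = 0.0
        for _ in range(3):  # alternate 1-D searches; converges fast in practice
            res = minimize_scalar(
                lambda p: -loglik_at(alpha, p), bounds=(0.0, 0.95),
                method="bounded", options={"xatol": 1e-4})
            p_inv = float(res.x)
            if -res.fun > best_ll:
                best_ll, best_pair = float(-res.fun), (alpha, p_inv)
            res = minimize_scalar(
                lambda a: -loglik_at(np.exp(a), p_inv), bounds=(np.log(0.02), np.log(50.0)),
                method="bounded", options={"xatol": 1e-3})
            alpha = float(np.exp(res.x))
            improved = float(-res.fun) - best_ll
            if -res.fun > best_ll:
                best_ll, best_pair = float(-res.fun), (alpha, p_inv)
            if improved < 1e-4:
                break
        return replace(model, alpha=best_pair[0], p_inv=best_pair[1]), best_ll
    if has_g:
        res = minimize_scalar(
            lambda a: -loglik_at(np.exp(a), None), bounds=(np.log(0.02), np.log(50.0)),
            method="bounded", options={"xatol": 1e-3})
        alpha = float(np.exp(res.x))
        return replace(model, alpha=alpha), loglik_at(alpha, None)
    if has_i:
        res = minimize_scalar(
            lambda p: -loglik_at(None, p), bounds=(0.0, 0.95), method="bounded",
            options={"xatol": 1e-4})
        p_inv = float(res.x)
        return replace(model, p_inv=p_inv), loglik_at(None, p_inv)
    return model, loglik_at(None, None)


def select_model(
    msa: Msa,
    tree: dendropy.Tree,
    candidates: Sequence[str | SubstitutionModel],
) -> tuple[SubstitutionModel, "pd.DataFrame"]:
    """Best-fit model by AIC on a fixed tree.

    Returns the winning instantiated model and a table (name, logL, k, AIC,
    delta_AIC) sorted by AIC.  k counts alpha, p_inv and (when +F) 19 free
    frequencies.  Ties break toward fewer parameters, then name.
    """
    import pandas as pd

    if not candidates:
        raise ValueError("no candidate models supplied")
    rows = []
    fitted: dict[int, SubstitutionModel] = {}
    for pos, cand in enumerate(candidates):
        model = model_from_name(cand, msa) if isinstance(cand, str) else cand
        model, loglik = _optimize_rate_params(tree, msa, model)
        k = model.n_free_params
        rows.append({"name": model.name, "logL": loglik, "k": k, "AIC": 2 * k - 2 * loglik, "pos": pos})
        fitted[pos] = model
    df = pd.DataFrame(rows)
    df["delta_AIC"] = df["AIC"] - df["AIC"].min()
    df = df.sort_values(["AIC", "k", "name", "pos"], kind="mergesort").reset_index(drop=True)
    best = fitted[int(df.loc[0, "pos"])]
    return best, df.drop(columns="pos")
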