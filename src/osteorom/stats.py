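"""Permutation MANOVA with randomization of residuals (RRPP).

Linear models with multivariate responses are evaluated term by term in
sequential (type-I) order. For each term the statistic is computed from the
incremental sums of squares and cross-products: ``SS = trace of the SSCP``
captured by the term's incremental column space, ``R^2 = SS / total SS``
and a pseudo-F with the full-model residual mean square. Significance is
assessed by randomizing the residuals of the reduced model (the terms
entered before the one under test): full response rows of the reduced-model
residuals are permuted, added back to the reduced-model fit, and the
statistic recomputed, with

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

Nested factors are written with the ``/`` operator (``Group/Species``
expands to ``Group + Group:Species``), crossing with ``*`` and plain
interactions with ``:``. The two standard designs are

    y ~ Group/Species * Region        (functional regionalization)
    y ~ Species * Arm                 (paired structure-removal)

Deterministic given the seed; the permutation count defaults to 10 000.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_N_PERM = 10_000


class DesignError(ValueError):
    """Invalid model design (aliased terms, constant response, ...)."""


# ---------------------------------------------------------------------------
# formula parsing


def parse_formula(formula: str) -> tuple[list[str] | None, list[tuple[str, ...]]]:
    """Parse ``y ~ rhs`` into (response names or None, ordered term list).

    Operators: ``+`` (addition), ``:`` (interaction), ``*`` (crossing,
    ``a*b = a + b + a:b``) and ``/`` (nesting, ``a/b = a + a:b``).
    """
    if "~" in formula:
        lhs, rhs = formula.split("~", 1)
        lhs = lhs.strip()
        responses = None if lhs in ("y", "") else [s.strip() for s in lhs.split("+")]
    else:
        responses, rhs = None, formula

    tokens = re.findall(r"[A-Za-z_]\w*|[+*/:()]", rhs)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def atom() -> list[tuple[str, ...]]:
        tok = take()
        if tok == "(":
            out = expr()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in {formula!r}")
            take()
            return out
        return [(tok,)]

    def interaction() -> list[tuple[str, ...]]:
        out = atom()
        while peek() == ":":
            take()
            right = atom()
            out = [a + b for a in out for b in right]
        return out

    def cross() -> list[tuple[str, ...]]:
        out = interaction()
        while peek() in ("*", "/"):
            op = take()
            right = interaction()
            if op == "*":
                out = out + right + [a + b for a in out for b in right]
            else:  # nesting: a / b -> a + a:b
                out = out + [a + b for a in out for b in right]
        return out

    def expr() -> list[tuple[str, ...]]:
        out = cross()
        while peek() == "+":
            take()
            out = out + cross()
        return out

    terms = expr()
    if pos != len(tokens):
        raise ValueError(f"could not parse formula {formula!r}")
    # de-duplicate keeping first occurrence
    seen, ordered = set(), []
    for t in terms:
        key = tuple(sorted(t))
        if key not in seen:
            seen.add(key)
            ordered.append(t)
    return responses, ordered


def _term_columns(data: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    """Full indicator coding of a (possibly interaction) term."""
    for f in term:
        if f not in data.columns:
            raise DesignError(f"factor {f!r} not in data")
    combo = data[list(term)].astype(str).agg(":".join, axis=1)
    codes, _ = pd.factorize(combo)
    n_levels = codes.max() + 1
    out = np.zeros((len(data), n_levels))
    out[np.arange(len(data)), codes] = 1.0
    return out


@dataclass
class ModelSpec:
    """A fitted-design description for the RRPP MANOVA."""

    data: pd.DataFrame
    responses: list[str]
    formula: str
    n_perm: int = DEFAULT_N_PERM
    seed: int | None = None
    terms: list[tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        _, self.terms = parse_formula(self.formula)


def _orthonormal_blocks(data: pd.DataFrame, terms) -> tuple[list[np.ndarray], list[int]]:
    """Incremental orthonormal bases per term (after the intercept)."""
    n = len(data)
    basis = np.ones((n, 1)) / np.sqrt(n)  # intercept
    blocks, dfs = [], []
    for term in terms:
        X = _term_columns(data, term)
        resid = X - basis @ (basis.T @ X)
        q, r = np.linalg.qr(resid)
        keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
        qi = q[:, keep]
        if qi.shape[1] == 0:
            raise DesignError(
                f"term {':'.join(term)} is aliased with earlier terms (rank 0)"
            )
        blocks.append(qi)
        dfs.append(qi.shape[1])
        basis = np.hstack([basis, qi])
    return blocks, dfs


def rrpp_manova(
    data: pd.DataFrame,
    responses: list[str] | None = None,
    formula: str = "y ~ Group/Species * Region",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> pd.DataFrame:
    """Residual-randomization permutation MANOVA.

    ``data`` holds the factor columns and response columns (complete
    cases). Returns one row per term: df, SS, R2, F and the permutation
    p-value; the seed and permutation count are recorded in ``attrs``.
    """
    resp_from_formula, terms = parse_formula(formula)
    responses = responses or resp_from_formula
    if not responses:
        raise ValueError("no response columns given")
    work = data.dropna(subset=list(responses)).reset_index(drop=True)
    Y = work[list(responses)].to_numpy(dtype=float)
    n, q = Y.shape
    if n <= len(terms) + 1:
        raise DesignError("more model terms than observations")
    if np.any(Y.std(axis=0) == 0):
        zero = [r for r, s in zip(responses, Y.std(axis=0)) if s == 0]
        raise DesignError(f"zero-variance response column(s): {zero}")
    for term in terms:
        for f in term:
            if work[f].nunique() < 2 and len(term) == 1:
                raise DesignError(f"factor {f!r} has fewer than 2 levels")

    blocks, dfs = _orthonormal_blocks(work, terms)
    basis_all = np.hstack([np.ones((n, 1)) / np.sqrt(n)] + blocks)
    rank_total = basis_all.shape[1]
    df_resid = n - rank_total
    if df_resid <= 0:
        raise DesignError("saturated design: no residual degrees of freedom")

    Yc = Y - Y.mean(axis=0)
    ss_total = float(np.sum(Yc**2))
    sse_full = float(np.sum(Y**2) - np.sum((basis_all.T @ Y) ** 2))
    mse_full = sse_full / df_resid

    ss_obs = np.array([float(np.sum((qi.T @ Y) ** 2)) for qi in blocks])
    f_obs = (ss_obs / np.array(dfs)) / mse_full

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    p_values = []
    for i, qi in enumerate(blocks):
        basis_red = np.hstack([np.ones((n, 1)) / np.sqrt(n)] + blocks[:i])
        fit_red = basis_red @ (basis_red.T @ Y)
        resid_red = Y - fit_red
        count = 0
        chunk = max(1, int(2e7 // (n * q)))
        for lo in range(0, n_perm, chunk):
            pr = perms[lo : lo + chunk]
            Ystar = fit_red[None, :, :] + resid_red[pr]  # (m, n, q)
            ss_i = np.sum(np.einsum("nk,mnq->mkq", qi, Ystar) ** 2, axis=(1, 2))
            proj = np.einsum("nk,mnq->mkq", basis_all, Ystar)
            sse_star = np.sum(Ystar**2, axis=(1, 2)) - np.sum(proj**2, axis=(1, 2))
            f_star = (ss_i / dfs[i]) / (sse_star / df_resid)
            count += int(np.sum(f_star >= f_obs[i] - 1e-12))
        p_values.append((1 + count) / (1 + n_perm))

    table = pd.DataFrame(
        {
            "term": [":".join(t) for t in terms],
            "df": dfs,
            "SS": ss_obs,
            "R2": ss_obs / ss_total,
            "F": f_obs,
            "p": p_values,
        }
    ).set_index("term")
    table.loc["residual"] = [df_resid, sse_full, sse_full / ss_total, np.nan, np.nan]
    table.attrs["n_perm"] = n_perm
    table.attrs["seed"] = seed
    table.attrs["responses"] = list(responses)
    table.attrs["formula"] = formula
    return table


def region_manova(
    summary: pd.DataFrame,
    responses: list[str] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> pd.DataFrame:
    """The regionalization design ``y ~ Group/Species * Region`` on a tidy
    per-joint summary table (columns group, species, region + responses)."""
    responses = responses or ["lateral", "sagittal", "axial"]
    data = summary.rename(
        columns={"group": "Group", "species": "Species", "region": "Region"}
    )
    return rrpp_manova(
        data, responses, "y ~ Group/Species * Region", n_perm=n_perm, seed=seed
    )


def structure_manova(
    summary: pd.DataFrame,
    responses: list[str] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> pd.DataFrame:
    """The paired structure-removal design ``y ~ Species * Arm`` (columns
    species, arm + responses; arm = with/without the structure)."""
    responses = responses or ["lateral", "sagittal", "axial"]
    data = summary.rename(columns={"species": "Species", "arm": "Arm"})
    return rrpp_manova(data, responses, "y ~ Species * Arm", n_perm=n_perm, seed=seed)
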