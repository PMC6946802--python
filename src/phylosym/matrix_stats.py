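"""Permutation statistics on distance matrices.

Mantel, partial Mantel (Smouse-Long-Sokal residual form), multiple regression
on distance matrices (MRM), and PERMANOVA (Anderson's pseudo-F).  All tests
permute object labels — rows and columns of one matrix jointly — never
triangle entries independently, and every permutation p-value includes the
observed statistic in its reference set, so the smallest attainable p is
1/(n_perm + 1).

Mantel-type tests default to the one-tailed (upper) alternative, matching the
directional phylosymbiosis hypothesis (closer hosts, more similar
microbiomes); the two-sided alternative is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_permutations

import numpy as np
from skbio import DistanceMatrix

from phylosym._seeding import substream

__all__ = [
    "MantelResult",
    "MrmResult",
    "PermanovaResult",
    "mantel",
    "partial_mantel",
    "mrm",
    "permanova",
]

#: tie tolerance when counting permuted statistics at least as extreme as the
#: observed one (guards the identity permutation against rounding)
_TIE_EPS = 1e-12


@dataclass
class MantelResult:
    r: float
    p: float
    slope: float
    n_perm: int
    n_objects: int


@dataclass
class MrmResult:
    r2: float
    coefficients: np.ndarray  # intercept first, then one per predictor
    p_overall: float
    p_coefficients: np.ndarray  # per non-intercept coefficient, by |t|
    n_perm: int
    n_objects: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    group_sizes: dict
    n_perm: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _aligned(*dms: DistanceMatrix) -> list[np.ndarray]:
    """Return the data of all matrices reordered to the first matrix's ids."""
    ref = dms[0]
    ids = list(ref.ids)
    out = [ref.data]
    for dm in dms[1:]:
        if set(dm.ids) != set(ids):
            raise ValueError("distance matrices have mismatched ids")
        out.append(dm.filter(ids).data if list(dm.ids) != ids else dm.data)
    return out


def _triangle(square: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(square.shape[0], k=1)
    return square[iu, ju]


def _standardize(v: np.ndarray, what: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(f"undefined correlation: {what} distance triangle is constant")
    return (v - v.mean()) / sd


def _permuted_triangles(square: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Triangles of label-permuted copies of ``square``; (n_perm, m)."""
    iu, ju = np.triu_indices(square.shape[0], k=1)
    return square[perms[:, iu], perms[:, ju]]


def _random_perms(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def _count_p(stats_perm: np.ndarray, observed: float, exhaustive: bool) -> float:
    hits = int(np.sum(stats_perm >= observed - _TIE_EPS))
    if exhaustive:  # the identity permutation is part of the enumeration
        return hits / len(stats_perm)
    return (1 + hits) / (1 + len(stats_perm))


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test: Pearson correlation of the two distance triangles.

    p is the fraction of label permutations of ``dy`` whose correlation is at
    least the observed one (one-tailed upper by default; ``alternative=
    "two-sided"`` compares |r|).  ``exhaustive=True`` enumerates all n! label
    permutations instead of sampling, yielding the exact permutation p.
    """
    x, y = _aligned(dx, dy)
    n = x.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 objects")
    tx, ty = _triangle(x), _triangle(y)
    zx = _standardize(tx, "dx")
    zy = _standardize(ty, "dy")
    r = float(np.mean(zx * zy))
    slope = float(np.polyfit(tx, ty, 1)[0])

    if exhaustive:
        perms = np.array(list(_all_permutations(range(n))))
    else:
        perms = _random_perms(n, n_perm, substream(seed, "mantel"))
    ty_perm = _permuted_triangles(y, perms)
    zy_perm = (ty_perm - ty_perm.mean(axis=1, keepdims=True)) / ty_perm.std(axis=1, keepdims=True)
    r_perm = zy_perm @ zx / len(zx)
    if alternative == "greater":
        p = _count_p(r_perm, r, exhaustive)
    elif alternative == "two-sided":
        p = _count_p(np.abs(r_perm), abs(r), exhaustive)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return MantelResult(r=r, p=float(p), slope=slope, n_perm=len(perms), n_objects=n)


def partial_mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    dz: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel: correlation of dx and dy with dz partialled out.

    Both triangles are regressed on the dz triangle; the partial r is the
    Pearson correlation of the residuals.  For inference the dx residuals are
    reshaped into a symmetric matrix whose object labels are permuted
    (Smouse-Long-Sokal).
    """
    x, y, z = _aligned(dx, dy, dz)
    n = x.shape[0]
    if n < 3:
        raise ValueError("partial Mantel test needs at least 3 objects")
    tx, ty = _triangle(x), _triangle(y)
    tz = _triangle(z)
    for name, t in (("dx", tx), ("dy", ty), ("dz", tz)):
        _standardize(t, name)  # reject constant triangles up front

    def _residual(t: np.ndarray) -> np.ndarray:
        slope, icept = np.polyfit(tz, t, 1)
        return t - (icept + slope * tz)

    rx, ry = _residual(tx), _residual(ty)
    # a residual variance at float-noise level means dz absorbs the matrix
    # entirely; the partial correlation is 0 by construction, not undefined
    if rx.std() <= 1e-12 * tx.std() or ry.std() <= 1e-12 * ty.std():
        return MantelResult(r=0.0, p=1.0, slope=0.0, n_perm=n_perm, n_objects=n)
    zr_x = _standardize(rx, "dx residual")
    zr_y = _standardize(ry, "dy residual")
    r = float(np.mean(zr_x * zr_y))
    slope = float(np.polyfit(rx, ry, 1)[0]) if rx.std() > 0 else float("nan")

    iu, ju = np.triu_indices(n, k=1)
    rx_sq = np.zeros((n, n))
    rx_sq[iu, ju] = rx
    rx_sq += rx_sq.T
    perms = _random_perms(n, n_perm, substream(seed, "partial_mantel"))
    rx_perm = _permuted_triangles(rx_sq, perms)
    zx_perm = (rx_perm - rx_perm.mean(axis=1, keepdims=True)) / rx_perm.std(axis=1, keepdims=True)
    r_perm = zx_perm @ zr_y / len(zr_y)
    if alternative == "greater":
        p = _count_p(r_perm, r, exhaustive=False)
    elif alternative == "two-sided":
        p = _count_p(np.abs(r_perm), abs(r), exhaustive=False)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return MantelResult(r=r, p=float(p), slope=slope, n_perm=n_perm, n_objects=n)


# ---------------------------------------------------------------------------
# MRM
# ---------------------------------------------------------------------------

def mrm(
    dy: DistanceMatrix,
    dxs: list[DistanceMatrix],
    n_perm: int = 999,
    seed: int | None = None,
    condition_threshold: float = 1e8,
) -> MrmResult:
    """Multiple regression of a distance triangle on predictor triangles.

    OLS with intercept on the vectorized upper triangles.  Inference permutes
    the object labels of ``dy`` jointly, recomputing R² (overall p) and |t|
    statistics (per-coefficient p), the scheme of the ecodist MRM.
    """
    if not dxs:
        raise ValueError("mrm needs at least one predictor matrix")
    mats = _aligned(dy, *dxs)
    y_sq, x_sqs = mats[0], mats[1:]
    n = y_sq.shape[0]
    ty = _triangle(y_sq)
    m = len(ty)
    X = np.column_stack([np.ones(m)] + [_triangle(x) for x in x_sqs])
    scaled = X.copy()
    norms = np.linalg.norm(scaled, axis=0)
    if (norms == 0).any() or np.linalg.cond(scaled / norms) > condition_threshold:
        raise ValueError("collinear predictor matrices (condition number above threshold)")

    pinv = np.linalg.pinv(X)
    hat = X @ pinv
    df = m - X.shape[1]
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))

    def _fit(yv: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        beta = pinv @ yv
        resid = yv - X @ beta
        sse = float(resid @ resid)
        sst = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        sigma2 = sse / df if df > 0 else np.nan
        se = np.sqrt(sigma2 * xtx_inv_diag)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf)
        return r2, beta, t

    r2, beta, t_obs = _fit(ty)

    perms = _random_perms(n, n_perm, substream(seed, "mrm"))
    ty_perm = _permuted_triangles(y_sq, perms)
    beta_perm = ty_perm @ pinv.T  # (n_perm, k+1)
    fitted = ty_perm @ hat.T
    sse_perm = ((ty_perm - fitted) ** 2).sum(axis=1)
    sst_perm = ((ty_perm - ty_perm.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    r2_perm = 1.0 - sse_perm / sst_perm
    sigma2_perm = sse_perm / df
    se_perm = np.sqrt(sigma2_perm[:, None] * xtx_inv_diag[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(se_perm > 0, beta_perm / se_perm, np.inf)

    p_overall = _count_p(r2_perm, r2, exhaustive=False)
    p_coef = np.array(
        [
            _count_p(np.abs(t_perm[:, k]), abs(t_obs[k]), exhaustive=False)
            for k in range(1, X.shape[1])
        ]
    )
    return MrmResult(
        r2=float(r2),
        coefficients=beta,
        p_overall=float(p_overall),
        p_coefficients=p_coef,
        n_perm=n_perm,
        n_objects=n,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)  # sum over i<j of d^2 / N
    ss_w = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        ss_w += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_a = ss_t - ss_w
    return (ss_a / (n_groups - 1)) / (ss_w / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with label permutation.

    ``groups`` maps the matrix ids to group labels: a dict/Series keyed by id
    or a sequence aligned with ``d.ids``.  R² is SS_between / SS_total.  If
    all off-diagonal distances are equal the result is flagged degenerate.
    """
    ids = list(d.ids)
    if hasattr(groups, "__getitem__") and not isinstance(groups, (list, tuple, np.ndarray)):
        labels = [groups[i] for i in ids]
    else:
        labels = list(groups)
        if len(labels) != len(ids):
            raise ValueError("groups length does not match distance matrix")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    n = len(ids)
    if n < 3:
        raise ValueError("PERMANOVA needs at least 3 objects")
    codes = np.array([uniq.index(l) for l in labels])
    d2 = d.data**2
    tri = _triangle(d.data)
    degenerate = bool(np.allclose(tri, tri[0]))

    ss_t = d2.sum() / (2.0 * n)
    f_obs = _permanova_f(d2, codes, len(uniq))
    ss_w = 0.0
    for g in range(len(uniq)):
        mask = codes == g
        ss_w += d2[np.ix_(mask, mask)].sum() / (2.0 * int(mask.sum()))
    r2 = (ss_t - ss_w) / ss_t if ss_t > 0 else 0.0

    rng = substream(seed, "permanova")
    f_perm = np.empty(n_perm)
    for i in range(n_perm):
        f_perm[i] = _permanova_f(d2, codes[rng.permutation(n)], len(uniq))
    p = _count_p(f_perm, f_obs, exhaustive=False)
    sizes = {u: int((codes == k).sum()) for k, u in enumerate(uniq)}
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(r2),
        p=float(p),
        group_sizes=sizes,
        n_perm=n_perm,
        degenerate=degenerate,
    )
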