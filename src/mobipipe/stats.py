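"""Inferential machinery: pointwise-t cluster maps with a consecutive-sample
run-length criterion, mixed repeated-measures ANOVA with Greenhouse-Geisser
correction and partial eta squared, Bonferroni post-hocs, Cohen's d, and the
pooled two-sample t.

The cluster procedure applies a two-tailed t-test at every channel x time
point and keeps only points lying in a same-channel run of at least
``min_run`` consecutive sub-alpha samples (10 samples at 512 Hz ~ 20 ms);
no spatial clustering across channels and no permutation step is involved.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ClusterMap",
    "EffectSize",
    "pointwise_t_map",
    "runlength_mask",
    "cluster_contrast_suite",
    "mixed_rm_anova",
    "gg_epsilon",
    "partial_eta_sq",
    "cohens_d",
    "cohens_d_paired",
    "student_t_two_sample",
    "bonferroni",
    "pairwise_posthoc",
]


# ---------------------------------------------------------------------------
# cluster maps
# ---------------------------------------------------------------------------


@dataclass
class ClusterMap:
    """Channels x time t/p maps with a run-length-filtered significance mask."""

    t_values: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray
    alpha: float
    min_run: int
    contrast: str = ""
    channel_labels: list = field(default_factory=list)
    time_ms: np.ndarray | None = None

    @property
    def n_significant(self):
        return int(self.mask.sum())


def _paired_t(A, B):
    d = A - B
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero] = 0.0
    df = n - 1
    return t, df, zero


def _two_sample_t(A, B):
    n1, n2 = A.shape[0], B.shape[0]
    v1 = A.var(axis=0, ddof=1)
    v2 = B.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    zero = sp2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(
            sp2 * (1.0 / n1 + 1.0 / n2)
        )
    t[zero] = 0.0
    df = n1 + n2 - 2
    return t, df, zero


def pointwise_t_map(A, B, design="paired", alpha=0.05, min_run=10,
                    contrast="", channel_labels=None, time_ms=None):
    """Two-tailed t-test at every channel x time point of two subject stacks.

    ``A`` and ``B`` are subjects x channels x time; ``paired`` tests the
    within-subject differences, ``two_sample`` uses the pooled-variance t.
    Points with zero variance get t = 0 and p = 1 (with a warning), keeping
    grid shapes stable.  The returned map already carries the run-length
    mask (see :func:`runlength_mask`).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 3 or B.ndim != 3 or A.shape[1:] != B.shape[1:]:
        raise ValueError("A and B must be subjects x channels x time with "
                         "matching grids")
    if design == "paired":
        if A.shape[0] != B.shape[0]:
            raise ValueError("paired design needs equal subject counts")
        if A.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        t, df, zero = _paired_t(A, B)
    elif design == "two_sample":
        if min(A.shape[0], B.shape[0]) < 3:
            raise ValueError("need at least 3 subjects per group")
        t, df, zero = _two_sample_t(A, B)
    else:
        raise ValueError("design must be 'paired' or 'two_sample'")
    p = 2.0 * sps.t.sf(np.abs(t), df)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} grid point(s) with zero variance; "
                      f"p set to 1 there")
        p[zero] = 1.0
    mask = runlength_mask(p, alpha, min_run)
    return ClusterMap(t, p, mask, alpha, min_run, contrast,
                      list(channel_labels or []), time_ms)


def runlength_mask(p_values, alpha=0.05, min_run=10):
    """Keep only same-channel runs of >= ``min_run`` consecutive p < alpha.

    Runs never span channels.  Shrinking ``alpha`` or growing ``min_run``
    can only remove points (monotonicity).
    """
    p = np.atleast_2d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sub = p < alpha
    mask = np.zeros_like(sub)
    n_ch, n_t = sub.shape
    for ch in range(n_ch):
        row = sub[ch]
        # run starts/ends via edge detection
        padded = np.concatenate([[False], row, [False]])
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0]
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                mask[ch, s:e] = True
    return mask if np.asarray(p_values).ndim == 2 else mask[0]


def cluster_contrast_suite(cells, groups=("TD", "ASD"),
                           conditions=("S-NF-T", "W-NF-T", "W-F-T"),
                           alpha=0.05, min_run=10, channel_labels=None,
                           time_ms=None):
    """The study's nine cluster analyses.

    ``cells[(group, condition)]`` maps to ``{"Hit": stack, "CR": stack}``
    of per-subject average waveforms (subjects x channels x time, subject
    order consistent between Hit and CR within a cell).  Produces the six
    within-group Hit-vs-CR paired maps (2 groups x 3 task conditions) plus
    three between-group two-sample maps on the per-subject CR - Hit
    difference.  Cells that are missing or incomplete skip their map with
    a logged reason.
    """
    maps = {}
    skipped = {}
    for group, cond in itertools.product(groups, conditions):
        cell = cells.get((group, cond))
        if not cell or "Hit" not in cell or "CR" not in cell:
            skipped[(group, cond)] = "missing Hit or CR stack"
            continue
        try:
            maps[(group, cond)] = pointwise_t_map(
                cell["CR"], cell["Hit"], "paired", alpha, min_run,
                contrast=f"{group} {cond} CR-vs-Hit",
                channel_labels=channel_labels, time_ms=time_ms,
            )
        except ValueError as exc:
            skipped[(group, cond)] = str(exc)
    label = f"{groups[0]}_vs_{groups[1]}"
    for cond in conditions:
        diffs = []
        for group in groups[:2]:
            cell = cells.get((group, cond))
            if not cell or "Hit" not in cell or "CR" not in cell:
                diffs = None
                break
            diffs.append(np.asarray(cell["CR"]) - np.asarray(cell["Hit"]))
        if diffs is None:
            skipped[(label, cond)] = "missing group cell"
            continue
        try:
            maps[(label, cond)] = pointwise_t_map(
                diffs[0], diffs[1], "two_sample", alpha, min_run,
                contrast=f"{label} {cond} (CR-Hit) difference",
                channel_labels=channel_labels, time_ms=time_ms,
            )
        except ValueError as exc:
            skipped[(label, cond)] = str(exc)
    if skipped:
        warnings.warn(f"skipped cluster maps: {skipped}")
    return maps


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k):
    """(k-1) x k orthonormal rows spanning the mean-zero subspace (Helmert)."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def gg_epsilon(cov):
    """Greenhouse-Geisser epsilon of a k-level within-factor covariance.

    Operates on the double-centered covariance; bounded by 1/(k-1) below
    and 1 above (1 exactly under compound symmetry).
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if S.shape != (k, k) or k < 2:
        raise ValueError("covariance must be square with k >= 2")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    C = np.eye(k) - np.ones((k, k)) / k
    M = C @ S @ C
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _epsilon_from_scores(resid):
    """GG epsilon from contrast-score residuals (subjects x d)."""
    d = resid.shape[1]
    if d < 2:
        return 1.0
    S = resid.T @ resid / max(1, resid.shape[0])
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr**2 / (d * tr2), 1.0 / d, 1.0))


def partial_eta_sq(ss_effect, ss_error):
    """Partial eta squared: SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect + ss_error == 0:
        return 0.0
    return float(ss_effect / (ss_effect + ss_error))


def mixed_rm_anova(data, dv, subject, within, between=None, order=None):
    """Mixed repeated-measures ANOVA (univariate approach).

    Parameters
    ----------
    data : DataFrame in long format, one row per subject x within-cell.
    dv, subject : column names.
    within : str or list of 1-2 column names (2-3 levels each).
    between : optional column name (the group factor).
    order : optional ``{factor: [levels...]}`` fixing level order.

    Returns a table with one row per effect: SS, df1, df2, MS, F,
    p_uncorrected, gg_epsilon, p_gg, partial_eta_sq.  The design must be
    complete and balanced within subjects (every subject measured in every
    within-cell exactly once); missing cells raise an error naming them.
    Greenhouse-Geisser correction is applied whenever an effect's contrast
    dimension exceeds 1; for 1-df effects epsilon is identically 1.
    Group combination uses unweighted (Type III) means, so unequal group
    sizes are handled as in standard statistical packages.
    """
    if isinstance(within, str):
        within = [within]
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name 1 or 2 factors")
    order = order or {}

    levels = {}
    for f in within:
        levels[f] = list(order.get(f, pd.unique(data[f])))
        if not 2 <= len(levels[f]) <= 3:
            raise ValueError(f"within factor {f!r} must have 2-3 levels")

    cell_cols = within
    cells = list(itertools.product(*(levels[f] for f in within)))
    pivot = data.pivot_table(index=subject, columns=cell_cols, values=dv,
                             aggfunc="mean", dropna=False)
    if len(within) == 1:
        pivot = pivot.reindex(columns=cells if len(within) > 1
                              else levels[within[0]])
    else:
        pivot = pivot.reindex(columns=pd.MultiIndex.from_tuples(cells))
    if pivot.isna().any().any():
        bad = [(str(s), str(c)) for s, c in
               zip(*np.nonzero(pivot.isna().to_numpy()))]
        raise ValueError(f"incomplete within-subject cells (subject row, "
                         f"cell column indices): {bad[:10]}")
    counts = data.groupby([subject] + cell_cols, observed=True)[dv].count()
    if (counts > 1).any():
        raise ValueError("multiple observations per subject x cell; "
                         "aggregate first")

    Y = pivot.to_numpy(dtype=float)
    subjects = pivot.index
    N = len(subjects)

    if between is not None:
        grp = data.drop_duplicates(subject).set_index(subject)[between]
        grp = grp.reindex(subjects)
        glevels = list(order.get(between, pd.unique(grp)))
        G = len(glevels)
        if G != 2:
            raise ValueError("the between factor must have exactly 2 levels")
        gidx = [np.nonzero((grp == g).to_numpy())[0] for g in glevels]
        ns = np.array([len(ix) for ix in gidx])
        if ns.min() < 2:
            raise ValueError("need at least 2 subjects per group")
    else:
        glevels = ["all"]
        gidx = [np.arange(N)]
        ns = np.array([N])
        G = 1

    k = [len(levels[f]) for f in within]
    Q = [_orthonormal_contrasts(kk) for kk in k]
    m = [np.full((1, kk), 1.0 / np.sqrt(kk)) for kk in k]

    rows = []

    def add_row(name, ss, df1, ss_err, df_err, eps):
        ms = ss / df1
        ms_err = ss_err / df_err
        F = ms / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(F, df1, df_err))
        p_gg = float(sps.f.sf(F, df1 * eps, df_err * eps))
        rows.append({
            "effect": name, "SS": ss, "df1": df1, "df2": df_err, "MS": ms,
            "SS_error": ss_err, "MS_error": ms_err, "F": F,
            "p_uncorrected": p, "gg_epsilon": eps, "p_gg": p_gg,
            "partial_eta_sq": partial_eta_sq(ss, ss_err),
        })

    # between-subjects stratum: subject means across cells (scaled)
    C0 = m[0] if len(within) == 1 else np.kron(m[0], m[1])
    u = (Y @ C0.T).ravel()
    gmeans = np.array([u[ix].mean() for ix in gidx])
    ss_sub_err = sum(((u[ix] - gm) ** 2).sum() for ix, gm in zip(gidx, gmeans))
    df_sub_err = N - G
    if between is not None:
        grand_w = (ns * gmeans).sum() / N
        ss_b = float((ns * (gmeans - grand_w) ** 2).sum())
        add_row(between, ss_b, G - 1, ss_sub_err, df_sub_err, 1.0)

    # within strata: each subset of within factors forms one error stratum
    subsets = [(0,)] if len(within) == 1 else [(0,), (1,), (0, 1)]
    for subset in subsets:
        mats = [Q[j] if j in subset else m[j] for j in range(len(within))]
        C = mats[0] if len(mats) == 1 else np.kron(mats[0], mats[1])
        d = C.shape[0]
        U = Y @ C.T                                  # N x d scores
        ubars = [U[ix].mean(axis=0) for ix in gidx]
        resid = np.vstack([U[ix] - ub for ix, ub in zip(gidx, ubars)])
        ss_err = float((resid**2).sum())
        df_err = d * (N - G)
        eps = _epsilon_from_scores(resid) if d > 1 else 1.0

        name = ":".join(within[j] for j in subset)
        # Type III main effect: unweighted mean of group means
        gbar = np.mean(ubars, axis=0)
        ss_main = float(G**2 / (1.0 / ns).sum() * (gbar**2).sum())
        add_row(name, ss_main, d, ss_err, df_err, eps)
        if between is not None:
            diff = ubars[0] - ubars[1]
            ss_int = float((diff**2).sum() / (1.0 / ns[0] + 1.0 / ns[1]))
            add_row(f"{between}:{name}", ss_int, d * (G - 1), ss_err,
                    df_err, eps)

    table = pd.DataFrame(rows)
    table.attrs["subject_error"] = {"SS": float(ss_sub_err),
                                    "df": int(df_sub_err)}
    return table


# ---------------------------------------------------------------------------
# effect sizes, t-tests, post-hocs
# ---------------------------------------------------------------------------


@dataclass
class EffectSize:
    """Cohen's d with its ingredients."""

    kind: str
    value: float
    components: dict


def cohens_d(m1, s1, n1, m2, s2, n2):
    """Pooled-SD Cohen's d for two independent groups.

    ``d = (m1 - m2) / s_pooled`` with
    ``s_pooled**2 = ((n1-1)s1**2 + (n2-1)s2**2) / (n1+n2-2)``.
    Antisymmetric in group order.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return EffectSize("pooled_d", float((m1 - m2) / sp),
                      {"m1": m1, "s1": s1, "n1": n1,
                       "m2": m2, "s2": s2, "n2": n2, "s_pooled": float(sp)})


def cohens_d_paired(mean_diff, sd_diff, n):
    """Paired Cohen's d: mean difference over the SD of the differences."""
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    return EffectSize("paired_d", float(mean_diff / sd_diff),
                      {"mean_diff": mean_diff, "sd_diff": sd_diff, "n": n})


def student_t_two_sample(m1, s1, n1, m2, s2, n2):
    """Pooled-variance Student t from summary statistics.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2`` (two-tailed p).
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), df, p


def bonferroni(p_values, m=None):
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else p.size
    if m < 1:
        raise ValueError("need at least one comparison")
    return np.minimum(1.0, m * p)


def pairwise_posthoc(data, dv, factor, subject, paired=True):
    """All pairwise comparisons among a factor's levels.

    Paired comparisons (within factor) use the paired t and paired d;
    unpaired (between factor) use the pooled two-sample t and pooled d.
    Bonferroni correction runs over the full set of pairs.
    """
    levels = list(pd.unique(data[factor]))
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        if paired:
            wide = data.pivot_table(index=subject, columns=factor, values=dv,
                                    aggfunc="mean")[[a, b]].dropna()
            diff = wide[a] - wide[b]
            n = len(diff)
            t, p = sps.ttest_rel(wide[a], wide[b])
            d = cohens_d_paired(diff.mean(), diff.std(ddof=1), n).value
            df = n - 1
            ma, mb = wide[a].mean(), wide[b].mean()
            sa, sb = wide[a].std(ddof=1), wide[b].std(ddof=1)
        else:
            xa = data.loc[data[factor] == a, dv].dropna()
            xb = data.loc[data[factor] == b, dv].dropna()
            ma, mb = xa.mean(), xb.mean()
            sa, sb = xa.std(ddof=1), xb.std(ddof=1)
            t, df, p = student_t_two_sample(ma, sa, len(xa), mb, sb, len(xb))
            d = cohens_d(ma, sa, len(xa), mb, sb, len(xb)).value
        rows.append({"level_a": a, "level_b": b, "mean_a": ma, "sd_a": sa,
                     "mean_b": mb, "sd_b": sb, "t": float(t), "df": df,
                     "p": float(p), "cohens_d": d})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p"].to_numpy())
    return out
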