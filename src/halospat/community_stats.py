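"""Inferential statistics for multi-scale community composition.

Covers the statistical layer of the halite spatial survey: PERMANOVA on
dissimilarity matrices, Kruskal–Wallis group tests on alpha diversity,
ANCOM compositional enrichment (W statistic), within-slice standardization
of relative abundances, paired positional tests, abundance-versus-depth
trends, distance-scale decay of similarity, and the technical noise floor
from biological replicates.

Sample pairs are assigned to spatial-scale classes by the finest level of
the nested design they share: same nodule and vertical position → ~3 cm
(horizontal, across slices); same nodule → ~10 cm; same site → ~10 m;
same region → ~300 m; different regions → ~20 km.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .env_sensors import SmoothFit, kernel_smooth

__all__ = [
    "SCALE_CLASSES",
    "PermanovaResult",
    "ScaleDecayResult",
    "permanova",
    "group_alpha_test",
    "ancom",
    "slice_standardize",
    "position_test",
    "distance_trend",
    "pair_scale_label",
    "scale_decay",
    "replicate_dissimilarity",
]

#: Spatial-scale classes from finest to coarsest shared design level.
SCALE_CLASSES = ("3 cm", "10 cm", "10 m", "300 m", "20 km")


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _align_labels(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = [i for i in dm.ids if i not in groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        return groups.loc[list(dm.ids)].to_numpy()
    return np.asarray(groups)


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ssw = 0.0
    for g in uniq:
        idx = labels == g
        ssw += d2[np.ix_(idx, idx)].sum() / (2 * idx.sum())
    return ssw


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Pseudo-F is formed from among/within sums of squared dissimilarities;
    the p-value is (1 + #{permuted F ≥ observed}) / (1 + n_perm) under free
    permutation of sample labels.  Deterministic under ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = _align_labels(dm, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than two samples: {small}")

    d2 = dm.data**2
    n, a = len(labels), len(uniq)
    sst = d2.sum() / (2 * n)

    def pseudo_f(lab: np.ndarray) -> float:
        ssw = _ss_within(d2, lab, uniq)
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a)) if ssw > 0 else np.inf

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    exceed = sum(
        pseudo_f(rng.permutation(labels)) >= f_obs for _ in range(n_perm)
    )
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=(1 + exceed) / (1 + n_perm),
        n_permutations=n_perm,
        n_samples=n,
        n_groups=a,
    )


# ---------------------------------------------------------------------------
# Group alpha-diversity test

def group_alpha_test(values, groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) for alpha diversity across groups.

    Returns (H, p).  Identical values everywhere give H = 0, p = 1.
    """
    values = pd.Series(values)
    labels = pd.Series(groups)
    labels = labels.loc[values.index] if labels.index.equals(values.index) else labels
    arrays = [values[np.asarray(labels) == g].to_numpy() for g in pd.unique(labels)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# ANCOM

def ancom(
    table: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    test: str = "t",
    pseudocount: float = 1.0,
    cutoff: float = 0.7,
) -> pd.DataFrame:
    """Analysis of composition of microbiomes (ANCOM) W statistic.

    For every ordered taxon pair (i, j) the per-sample additive log-ratio
    log((xᵢ+pc)/(xⱼ+pc)) is tested for a group difference; each taxon's
    pairwise p-value family is Benjamini–Hochberg corrected, and Wᵢ counts
    rejections at ``alpha``.  A taxon is flagged when
    W ≥ cutoff · (n_taxa − 1).

    ``test``: 't' (Student, pooled variance; ANOVA for >2 groups) or 'mw'
    (Mann–Whitney; Kruskal–Wallis for >2 groups).
    """
    labels = _table_labels(table, groups)
    zero = table.columns[(table == 0).all(axis=0)]
    if len(zero):
        warnings.warn(
            f"dropping {len(zero)} all-zero taxa before ANCOM", stacklevel=2
        )
        table = table.drop(columns=zero)
    m = table.shape[1]
    if m < 2:
        raise ValueError("ANCOM needs at least two taxa with non-zero counts")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")

    logs = np.log(table.to_numpy(dtype=float) + pseudocount)
    group_masks = [np.asarray(labels) == g for g in uniq]

    pvals = np.full((m, m), np.nan)
    for i, j in itertools.combinations(range(m), 2):
        ratio = logs[:, i] - logs[:, j]
        samples = [ratio[mask] for mask in group_masks]
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(ratio) == 0:
            p = 1.0
        elif test == "t":
            if len(samples) == 2:
                p = stats.ttest_ind(*samples, equal_var=True).pvalue
            else:
                p = stats.f_oneway(*samples).pvalue
        elif test == "mw":
            if len(samples) == 2:
                p = stats.mannwhitneyu(*samples, alternative="two-sided").pvalue
            else:
                p = stats.kruskal(*samples).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        if np.isnan(p):  # zero-variance degenerate comparison
            p = 1.0 if np.isclose(np.mean(samples[0]), np.mean(samples[-1])) else 0.0
        pvals[i, j] = pvals[j, i] = p

    w = np.zeros(m, dtype=int)
    for i in range(m):
        family = pvals[i, np.arange(m) != i]
        adj = stats.false_discovery_control(family)
        w[i] = int((adj < alpha).sum())
    return pd.DataFrame(
        {"W": w, "significant": w >= cutoff * (m - 1)}, index=table.columns
    )


def _table_labels(table: pd.DataFrame, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = table.index.difference(groups.index)
        if len(missing):
            raise ValueError(f"samples without group labels: {list(missing)}")
        return groups.loc[table.index].to_numpy()
    groups = np.asarray(groups)
    if len(groups) != len(table):
        raise ValueError("group labels must align with table rows")
    return groups


# ---------------------------------------------------------------------------
# Slice standardization and positional tests

def slice_standardize(rel_abund: pd.DataFrame, slices) -> pd.DataFrame:
    """Divide each taxon's relative abundance by its mean in the sample's
    slice.

    Within every slice the standardized values of a taxon with positive
    slice mean average exactly 1; taxa absent from a slice come out as NaN
    (missing, never infinite) for that slice.
    """
    labels = _table_labels(rel_abund, slices)
    slice_mean = rel_abund.groupby(labels, sort=False).transform("mean")
    out = rel_abund / slice_mean.where(slice_mean > 0)
    return out


def position_test(
    std: pd.DataFrame,
    positions,
    pairing,
    paired: bool = True,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-taxon positional contrasts of (standardized) abundances.

    For every unordered pair of position labels, samples are matched on the
    pairing unit (slice) — averaging replicates within a slice-position —
    and a two-sided paired Student t-test applied per taxon (``paired=False``
    gives the independent pooled-variance test used for site comparisons).
    Taxa with fewer than two complete pairs are reported with NaN statistics.
    Raw p-values are always reported; Benjamini–Hochberg adjusted p-values
    are added per contrast across taxa when ``adjust`` is True.
    """
    pos = pd.Series(_table_labels(std, positions), index=std.index)
    unit = pd.Series(_table_labels(std, pairing), index=std.index)
    rows = []
    for a, b in itertools.combinations(pd.unique(pos), 2):
        for taxon in std.columns:
            cell = std[taxon].groupby([unit, pos]).mean().unstack()
            if a not in cell.columns or b not in cell.columns:
                continue
            paired_vals = cell[[a, b]].dropna()
            va, vb = paired_vals[a].to_numpy(), paired_vals[b].to_numpy()
            if len(va) < 2:
                rows.append(_pos_row(taxon, a, b, len(va), np.nan, np.nan,
                                     np.nan, False, "fewer than two pairs"))
                continue
            diff = va - vb
            degenerate = False
            if paired:
                if np.ptp(diff) == 0:
                    degenerate = diff[0] != 0
                    t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
                else:
                    t, p = stats.ttest_rel(va, vb)
            else:
                av = np.concatenate([va, vb])
                if np.ptp(av) == 0:
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(va, vb, equal_var=True)
            rows.append(_pos_row(taxon, a, b, len(va), float(np.mean(diff)),
                                 float(t), float(p), degenerate, ""))
    result = pd.DataFrame(rows)
    if adjust and len(result):
        result["p_adj"] = np.nan
        for (a, b), idx in result.groupby(["position_a", "position_b"]).groups.items():
            ok = result.loc[idx, "p"].notna()
            if ok.any():
                result.loc[idx[ok], "p_adj"] = stats.false_discovery_control(
                    result.loc[idx[ok], "p"].to_numpy()
                )
    return result


def _pos_row(taxon, a, b, n, mean_diff, t, p, degenerate, note):
    return {
        "taxon": taxon, "position_a": a, "position_b": b, "n_pairs": n,
        "mean_diff": mean_diff, "t": t, "p": p,
        "degenerate": degenerate, "note": note,
    }


# ---------------------------------------------------------------------------
# Distance-to-surface trends

@dataclass
class TrendResult:
    """Per-taxon abundance-versus-depth trend."""

    taxon: str
    rho: float
    rho_p: float
    split_t: float
    split_p: float
    n_near: int
    n_interior: int
    curve: SmoothFit = field(repr=False)


def distance_trend(
    std: pd.DataFrame,
    distance,
    pairing=None,
    split_cm: float = 1.5,
    bandwidth: float = 0.5,
    grid=None,
) -> list[TrendResult]:
    """Correlate (standardized) abundances with distance to the nodule
    surface.

    Per taxon: Spearman ρ with its p-value; a local-average smoothed curve
    (order-0 kernel regression) of abundance versus distance; and a
    two-sided t-test contrasting the near-surface (< ``split_cm``) and
    interior halves — paired on ``pairing`` (slice) means when given, else
    independent.  Taxa with constant abundance get NaN statistics.
    """
    d = pd.Series(np.asarray(distance, dtype=float), index=std.index)
    if d.nunique() < 4:
        raise ValueError("need at least four distinct distances")
    if grid is None:
        grid = np.linspace(d.min(), d.max(), 60)
    near = d < split_cm

    results = []
    for taxon in std.columns:
        v = std[taxon]
        ok = v.notna()
        if ok.sum() < 4 or np.ptp(v[ok].to_numpy()) == 0:
            rho = rho_p = split_t = split_p = np.nan
            curve = SmoothFit(np.asarray(grid), np.full(len(np.atleast_1d(grid)), np.nan),
                              np.zeros(len(np.atleast_1d(grid)), dtype=int))
            results.append(TrendResult(taxon, rho, rho_p, split_t, split_p,
                                       int(near[ok].sum()), int((~near)[ok].sum()),
                                       curve))
            continue
        rho, rho_p = stats.spearmanr(d[ok], v[ok])
        curve = kernel_smooth(d[ok].to_numpy(), v[ok].to_numpy(),
                              bandwidth=bandwidth, order=0, x_query=grid)
        va, vb = v[ok & near], v[ok & ~near]
        if pairing is not None:
            unit = pd.Series(_table_labels(std, pairing), index=std.index)
            half = near.map({True: "near", False: "interior"})
            per_unit = v[ok].groupby([unit[ok], half[ok]]).mean().unstack()
            if {"near", "interior"} <= set(per_unit.columns):
                both = per_unit[["near", "interior"]].dropna()
                va, vb = both["near"], both["interior"]
        if len(va) >= 2 and len(vb) >= 2 and np.ptp(np.concatenate([va, vb])) > 0:
            if pairing is not None and len(va) == len(vb):
                split_t, split_p = stats.ttest_rel(va, vb)
            else:
                split_t, split_p = stats.ttest_ind(va, vb, equal_var=True)
        else:
            split_t = split_p = np.nan
        results.append(TrendResult(taxon, float(rho), float(rho_p),
                                   float(split_t), float(split_p),
                                   int(len(va)), int(len(vb)), curve))
    return results


# ---------------------------------------------------------------------------
# Distance-scale decay

def pair_scale_label(row_a: pd.Series, row_b: pd.Series) -> str | None:
    """Scale class of a sample pair from its nested design labels.

    Labels must include region, site, nodule, position; returns None when a
    required label is missing.
    """
    needed = ("region", "site", "nodule", "position")
    if any(pd.isna(row_a.get(k)) or pd.isna(row_b.get(k)) for k in needed):
        return None
    if row_a["nodule"] == row_b["nodule"]:
        if row_a["position"] == row_b["position"]:
            return "3 cm"
        return "10 cm"
    if row_a["site"] == row_b["site"]:
        return "10 m"
    if row_a["region"] == row_b["region"]:
        return "300 m"
    return "20 km"


@dataclass
class ScaleDecayResult:
    """Dissimilarity distributions per spatial-scale class."""

    classes: dict[str, np.ndarray]
    tests: pd.DataFrame
    n_excluded: int

    def means(self) -> pd.Series:
        return pd.Series(
            {k: (v.mean() if len(v) else np.nan) for k, v in self.classes.items()}
        )


def scale_decay(dm: DistanceMatrix, metadata: pd.DataFrame) -> ScaleDecayResult:
    """Distance-decay analysis: classify every sample pair by spatial scale
    and compare adjacent scale classes.

    Each pair is assigned to exactly one of the classes in
    :data:`SCALE_CLASSES` by the finest shared design level; pairs with
    incomplete labels are excluded and counted.  Adjacent classes are
    compared with two-sided Student t-tests on their dissimilarity
    distributions.
    """
    missing = [i for i in dm.ids if i not in metadata.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    meta = metadata.loc[list(dm.ids)]
    needed = ["region", "site", "nodule", "position"]
    codes = {}
    complete = np.ones(len(meta), dtype=bool)
    for col in needed:
        vals = meta[col]
        complete &= vals.notna().to_numpy()
        codes[col] = pd.factorize(vals)[0]

    n = len(meta)
    classes: dict[str, list] = {k: [] for k in SCALE_CLASSES}
    n_excluded = 0
    d = dm.data
    for i, j in itertools.combinations(range(n), 2):
        if not (complete[i] and complete[j]):
            n_excluded += 1
            continue
        if codes["nodule"][i] == codes["nodule"][j]:
            label = "3 cm" if codes["position"][i] == codes["position"][j] else "10 cm"
        elif codes["site"][i] == codes["site"][j]:
            label = "10 m"
        elif codes["region"][i] == codes["region"][j]:
            label = "300 m"
        else:
            label = "20 km"
        classes[label].append(d[i, j])

    arrays = {k: np.asarray(v) for k, v in classes.items()}
    rows = []
    present = [k for k in SCALE_CLASSES if len(arrays[k]) > 0]
    for a, b in zip(present[:-1], present[1:]):
        va, vb = arrays[a], arrays[b]
        if len(va) >= 2 and len(vb) >= 2 and np.ptp(np.concatenate([va, vb])) > 0:
            t, p = stats.ttest_ind(va, vb, equal_var=True)
        else:
            t, p = (0.0, 1.0)
        rows.append({"class_a": a, "class_b": b, "t": float(t), "p": float(p),
                     "n_a": len(va), "n_b": len(vb)})
    return ScaleDecayResult(
        classes=arrays,
        tests=pd.DataFrame(rows, columns=["class_a", "class_b", "t", "p", "n_a", "n_b"]),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Replicate noise floor

def replicate_dissimilarity(dm: DistanceMatrix, pairs) -> tuple[float, float]:
    """Mean ± SD dissimilarity over listed biological-replicate pairs — the
    pipeline's technical noise floor.  SD is NaN for a single pair."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no replicate pairs given")
    vals = np.array([dm[a, b] for a, b in pairs])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return float(vals.mean()), sd
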