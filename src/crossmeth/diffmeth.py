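"""Differential methylation via per-unit binomial logistic regression.

The caller mirrors the methylKit-style pipeline: per-sample coverage
filtering (>=10x and below the 99.9th coverage percentile), median-scaling
coverage normalization, destranded uniting with a per-group minimum sample
count, optional 1-kb tiling, and at every unit a logistic fit of the
methylation proportion on the group indicator with sex as a covariate:

    logit(P_i) = beta0 + beta1 * T_i + a_sex * Sex_i

with T_i = 0 for the control group (the breed matching the reference
genome) and 1 for treatment, Sex_i 0 = male / 1 = female. Significance is
the 1-df likelihood-ratio chi-square for beta1; the methylation difference
is the pooled treatment minus pooled control proportion in percentage
points. q-values are Benjamini-Hochberg. DMRs/DMCs are the units with
|diff| >= 10 percentage points and q <= 0.01.

The per-unit fits are solved by a batched IRLS written here (all units
advance together through vectorized Newton steps); statsmodels' GLM serves
as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import MethylationCallSet

GROUPS = ("BTBT", "BTBI", "BIBT", "BIBI")


@dataclass
class DMRParams:
    win_size: int = 1_000
    step: int = 1_000
    min_diff_pct: float = 10.0
    max_q: float = 0.01
    min_cov: int = 10
    max_cov_percentile: float = 99.9
    min_per_group: int = 5

    def __post_init__(self) -> None:
        if self.step != self.win_size:
            raise ValueError("tiling windows are non-overlapping: step must equal win_size")


@dataclass
class DesignInfo:
    samples: list[str]
    T: np.ndarray    # 0 control / 1 treatment
    Sex: np.ndarray  # 0 male / 1 female
    control_groups: tuple[str, ...] = ()
    treatment_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.T == 0).sum() == 0 or (self.T == 1).sum() == 0:
            raise ValueError("both control and treatment groups must be non-empty")


def contrast_groups(contrast: str, reference: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(control, treatment) group labels for the three standard designs.

    Group labels are sire-breed + dam-breed (BT = taurine/Angus, BI =
    indicine/Brahman). The control side is the one containing the purebred
    matching the reference genome.
    """
    ref = reference.lower()
    ref_pure = "BIBI" if ("brahman" in ref or ref in ("bi", "bibi")) else "BTBT"
    other_pure = "BTBT" if ref_pure == "BIBI" else "BIBI"
    if contrast == "breed":
        return (ref_pure,), (other_pure,)
    if contrast == "dam":
        sides = ({"BIBI", "BTBI"}, {"BTBT", "BIBT"})  # BI dams vs BT dams
    elif contrast == "sire":
        sides = ({"BIBI", "BIBT"}, {"BTBT", "BTBI"})  # BI sires vs BT sires
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    ctrl = sides[0] if ref_pure in sides[0] else sides[1]
    treat = sides[1] if ctrl is sides[0] else sides[0]
    return tuple(sorted(ctrl)), tuple(sorted(treat))


def make_design(sample_sheet: pd.DataFrame, control_groups, treatment_groups) -> DesignInfo:
    sel = sample_sheet[sample_sheet["group"].isin(set(control_groups) | set(treatment_groups))]
    T = sel["group"].isin(set(treatment_groups)).astype(int).to_numpy()
    Sex = sel["sex"].map({"M": 0, "F": 1}).to_numpy()
    return DesignInfo(sel["sample_id"].tolist(), T, Sex,
                      tuple(control_groups), tuple(treatment_groups))


# ---------------------------------------------------------------- uniting


@dataclass
class UnitedCounts:
    units: pd.DataFrame         # chrom, start0, end0
    coverage: np.ndarray        # units x samples, 0 where the sample lacks the unit
    n_meth: np.ndarray
    samples: list[str]
    level: str = "site"


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def prepare_counts(callsets: list[MethylationCallSet], sample_sheet: pd.DataFrame,
                   design: DesignInfo, params: DMRParams | None = None) -> UnitedCounts:
    """Filter, normalize, destrand and unite per-sample call sets.

    Order of operations: per-sample coverage filter (>= min_cov and <= the
    sample's 99.9th coverage percentile) on stranded rows, median-scaling
    normalization (counts scaled by median-of-medians / sample median,
    rounded half-up, methylation proportion preserved), destrand merge
    (reverse-strand cytosines fold onto the forward C of the dinucleotide),
    then unite keeping units covered in >= min_per_group samples of every
    group.
    """
    params = params or DMRParams()
    by_sample = {cs.sample_id: cs for cs in callsets}
    groups = dict(zip(sample_sheet["sample_id"], sample_sheet["group"]))
    for side, labels in (("control", design.control_groups), ("treatment", design.treatment_groups)):
        n = sum(1 for s in design.samples if groups[s] in labels)
        if n < params.min_per_group:
            raise ValueError(
                f"{side} side has {n} samples, fewer than min_per_group={params.min_per_group}"
            )

    filtered = {}
    medians = {}
    for sid in design.samples:
        d = by_sample[sid].df
        cap = np.percentile(d["coverage"], params.max_cov_percentile)
        d = d[(d["coverage"] >= params.min_cov) & (d["coverage"] <= cap)].copy()
        filtered[sid] = d
        medians[sid] = float(d["coverage"].median())
    grand = float(np.median(list(medians.values())))

    per_sample = {}
    for sid in design.samples:
        d = filtered[sid]
        scale = grand / medians[sid] if medians[sid] > 0 else 1.0
        cov = np.maximum(1, _round_half_up(d["coverage"].to_numpy() * scale))
        meth = np.minimum(cov, _round_half_up(d["n_meth"].to_numpy() * scale))
        pos = d["pos0"].to_numpy().copy()
        pos = np.where(d["strand"].to_numpy() == "-", pos - 1, pos)
        dd = pd.DataFrame({"chrom": d["chrom"].to_numpy(), "pos0": pos, "cov": cov, "meth": meth})
        dd = dd.groupby(["chrom", "pos0"], as_index=False).sum()
        per_sample[sid] = dd

    frames = [per_sample[sid].set_index(["chrom", "pos0"]) for sid in design.samples]
    all_idx = frames[0].index
    for f in frames[1:]:
        all_idx = all_idx.union(f.index)
    all_idx = all_idx.sortlevel()[0]
    cov = np.zeros((len(all_idx), len(design.samples)), dtype=np.int64)
    meth = np.zeros_like(cov)
    for j, f in enumerate(frames):
        sub = f.reindex(all_idx)
        cov[:, j] = sub["cov"].fillna(0).to_numpy()
        meth[:, j] = sub["meth"].fillna(0).to_numpy()

    present = cov > 0
    keep = np.ones(len(all_idx), dtype=bool)
    sample_groups = np.array([groups[s] for s in design.samples])
    for side in (design.control_groups, design.treatment_groups):
        for g in side:
            cols = sample_groups == g
            if cols.any():
                keep &= present[:, cols].sum(axis=1) >= min(params.min_per_group, int(cols.sum()))
    units = pd.DataFrame(
        {"chrom": all_idx.get_level_values(0), "start0": all_idx.get_level_values(1)}
    )
    units["end0"] = units["start0"] + 2
    return UnitedCounts(units[keep].reset_index(drop=True), cov[keep], meth[keep],
                        list(design.samples), level="site")


def tile_counts(united: UnitedCounts, design: DesignInfo, sample_sheet: pd.DataFrame,
                params: DMRParams | None = None) -> UnitedCounts:
    """Aggregate site-level counts into non-overlapping windows.

    Per window and sample, coverage and methylated counts are summed over
    contained sites; a sample covers a window when it covers at least one
    site in it; the min_per_group rule is re-applied at window level.
    Windows with no covered site are absent.
    """
    params = params or DMRParams()
    if united.level != "site":
        raise ValueError("tile_counts expects site-level united counts")
    win = params.win_size
    w = (united.units["start0"] // win) * win
    key = pd.DataFrame({"chrom": united.units["chrom"], "wstart": w})
    gid, uniq = pd.factorize(pd.MultiIndex.from_frame(key), sort=True)
    n_win = len(uniq)
    cov = np.zeros((n_win, len(united.samples)), dtype=np.int64)
    meth = np.zeros_like(cov)
    np.add.at(cov, gid, united.coverage)
    np.add.at(meth, gid, united.n_meth)
    units = pd.DataFrame({"chrom": [u[0] for u in uniq], "start0": [u[1] for u in uniq]})
    units["end0"] = units["start0"] + win
    groups = dict(zip(sample_sheet["sample_id"], sample_sheet["group"]))
    sample_groups = np.array([groups[s] for s in united.samples])
    present = cov > 0
    keep = np.ones(n_win, dtype=bool)
    for side in (design.control_groups, design.treatment_groups):
        for g in side:
            cols = sample_groups == g
            if cols.any():
                keep &= present[:, cols].sum(axis=1) >= min(params.min_per_group, int(cols.sum()))
    return UnitedCounts(units[keep].reset_index(drop=True), cov[keep], meth[keep],
                        united.samples, level="window")


# ---------------------------------------------------------------- logistic test


def _binom_deviance(K, C, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(K > 0, K * np.log(K / (C * mu)), 0.0)
        t2 = np.where(C - K > 0, (C - K) * np.log((C - K) / (C * (1 - mu))), 0.0)
    t1 = np.where(C > 0, t1, 0.0)
    t2 = np.where(C > 0, t2, 0.0)
    return 2.0 * (t1 + t2).sum(axis=1)


def _fit_logistic_batch(X: np.ndarray, C: np.ndarray, K: np.ndarray,
                        max_iter: int = 60, tol: float = 1e-10):
    """Batched IRLS for per-unit binomial logistic models sharing a design.

    C and K are units x samples trial/success counts (0 trials = sample
    absent at that unit). Returns (beta, deviance, converged).
    """
    U, S = C.shape
    P = X.shape[1]
    beta = np.zeros((U, P))
    p0 = np.clip((K.sum(1) + 0.5) / (C.sum(1) + 1.0), 1e-9, 1 - 1e-9)
    beta[:, 0] = np.log(p0 / (1 - p0))
    delta = np.full(U, np.inf)
    eye = np.eye(P) * 1e-8
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        Wt = C * mu * (1.0 - mu)
        score = (K - C * mu) @ X
        info = np.einsum("us,sp,sq->upq", Wt, X, X) + eye
        step = np.linalg.solve(info, score[..., None])[..., 0]
        step = np.clip(step, -8.0, 8.0)
        beta = beta + step
        delta = np.abs(step).max(axis=1)
        if (delta < tol).all():
            break
    eta = np.clip(beta @ X.T, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _binom_deviance(K, C, np.clip(mu, 1e-12, 1 - 1e-12))
    return beta, dev, delta < 1e-5


def logistic_diff_test(united: UnitedCounts, design: DesignInfo,
                       overdispersion: bool = False) -> pd.DataFrame:
    """Per-unit LR test of the group term; BH q-values across units.

    Non-converged units (typically complete separation) fall back to a
    Fisher exact test on the pooled 2x2 table and are flagged.
    With ``overdispersion`` the LR statistic is scaled by a per-unit Pearson
    dispersion estimate (floored at 1) before the chi-square lookup.
    """
    X1 = np.column_stack([np.ones_like(design.T, dtype=float), design.T, design.Sex])
    X0 = X1[:, [0, 2]]
    C = united.coverage.astype(float)
    K = united.n_meth.astype(float)
    beta1, dev1, conv1 = _fit_logistic_batch(X1, C, K)
    _b0, dev0, _c0 = _fit_logistic_batch(X0, C, K)
    stat = np.maximum(0.0, dev0 - dev1)

    if overdispersion:
        eta = np.clip(beta1 @ X1.T, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        with np.errstate(divide="ignore", invalid="ignore"):
            pe = np.where(C > 0, (K - C * mu) ** 2 / (C * mu * (1 - mu)), 0.0)
        n_eff = (C > 0).sum(axis=1) - X1.shape[1]
        phi = np.maximum(1.0, pe.sum(axis=1) / np.maximum(1, n_eff))
        stat = stat / phi

    p = sps.chi2.sf(stat, df=1)

    treat = design.T == 1
    ctrl = ~treat
    with np.errstate(invalid="ignore", divide="ignore"):
        p_t = K[:, treat].sum(1) / C[:, treat].sum(1)
        p_c = K[:, ctrl].sum(1) / C[:, ctrl].sum(1)
    diff = 100.0 * (p_t - p_c)

    flagged = ~conv1
    if flagged.any():
        for i in np.flatnonzero(flagged):
            table = [
                [K[i, treat].sum(), C[i, treat].sum() - K[i, treat].sum()],
                [K[i, ctrl].sum(), C[i, ctrl].sum() - K[i, ctrl].sum()],
            ]
            p[i] = sps.fisher_exact(table)[1]

    q = multipletests(p, method="fdr_bh")[1]
    out = united.units.copy()
    out["beta0"] = beta1[:, 0]
    out["beta1"] = beta1[:, 1]
    out["alpha_sex"] = beta1[:, 2]
    out["meth_diff_pct"] = diff
    out["p"] = p
    out["q"] = q
    out["direction"] = np.where(diff > 0, "hyper", "hypo")
    out["converged"] = conv1
    return out


def call_dmrs(results: pd.DataFrame, params: DMRParams | None = None) -> pd.DataFrame:
    """Threshold the per-unit results: |diff| >= min_diff_pct and q <= max_q."""
    params = params or DMRParams()
    keep = (results["meth_diff_pct"].abs() >= params.min_diff_pct) & (results["q"] <= params.max_q)
    return results[keep].reset_index(drop=True)
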