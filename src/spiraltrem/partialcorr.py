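"""Pearson partial correlation with covariate control.

The partial correlation of x and y given controls z₁…z_k is the Pearson
correlation of the residuals of x and y after ordinary least-squares
regression of each on [1, z₁…z_k].  For a single control the result equals
the closed form

    pc = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²))

and for k = 0 it degrades to the plain Pearson correlation.  Two-tailed
("bilateral") p-values come from t = pc·√(df / (1 − pc²)) with df = n−2−k
referred to Student's t, matching the convention of standard statistical
packages.  Cases with a missing value in any variable are dropped listwise
before anything is computed.

No multiple-testing correction is applied by default (results are flagged
at the uncorrected 0.05 and 0.01 bilateral thresholds); a Benjamini–Hochberg
adjusted column is available as an option on correlation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, SampleSizeError

ALPHA = 0.05
ALPHA_STRICT = 0.01


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial-correlation estimate for one variable pair.

    Attributes
    ----------
    pc : partial correlation in [−1, 1]
    p_value : two-tailed p-value
    n : number of complete cases used
    df : t-test degrees of freedom, n − 2 − k
    controls : names of the control variables
    sig_05, sig_01 : bilateral significance flags at 0.05 / 0.01
    """

    pc: float
    p_value: float
    n: int
    df: int
    controls: tuple[str, ...] = ()
    sig_05: bool = field(init=False, default=False)
    sig_01: bool = field(init=False, default=False)

    def __post_init__(self):
        object.__setattr__(self, "sig_05", self.p_value < ALPHA)
        object.__setattr__(self, "sig_01", self.p_value < ALPHA_STRICT)


def pvalue_from_pc(pc: float, n: int, k: int = 1) -> float:
    """Two-tailed p-value for a partial correlation with k controls.

    Uses t = pc·√(df/(1−pc²)), df = n−2−k.  pc = ±1 gives p = 0 and
    pc = 0 gives p = 1 exactly.
    """
    if abs(pc) > 1 + 1e-12:
        raise ValueError(f"|pc| must be <= 1, got {pc}")
    pc = float(np.clip(pc, -1.0, 1.0))
    df = n - 2 - k
    if df < 1:
        raise SampleSizeError(f"df = n - 2 - k = {df} < 1 (n={n}, k={k})")
    if abs(pc) == 1.0:
        return 0.0
    t = pc * np.sqrt(df / (1.0 - pc * pc))
    return float(2.0 * stats.t.sf(abs(t), df))


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_corr(
    x,
    y,
    controls=None,
    control_names: tuple[str, ...] | None = None,
) -> PartialCorrResult:
    """Partial correlation of x and y given zero or more control vectors.

    ``controls`` may be None (plain Pearson), a single vector, or a sequence
    of k vectors / a 2-d array with k columns.  Listwise deletion is applied
    first; every variable must be non-constant on the complete cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(controls, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        elif Z.shape[0] != len(x) and Z.shape[1] == len(x):
            Z = Z.T
    if len(y) != len(x) or Z.shape[0] != len(x):
        raise ValueError("x, y and controls must have equal length")
    k = Z.shape[1]
    if control_names is None:
        control_names = tuple(f"z{i + 1}" for i in range(k))

    complete = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[complete], y[complete], Z[complete]
    n = len(x)
    if n - 2 - k < 1:  # df must be >= 1
        raise SampleSizeError(f"need >= {k + 3} complete cases with {k} controls, got {n}")
    for name, v in (("x", x), ("y", y), *((control_names[j], Z[:, j]) for j in range(k))):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"variable {name!r} is constant on complete cases")

    design = np.column_stack([np.ones(n), Z])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    denom = np.sqrt(np.sum(rx * rx) * np.sum(ry * ry))
    if denom == 0:
        raise DegenerateInputError("residuals are degenerate (perfect fit by controls)")
    pc = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    return PartialCorrResult(
        pc=pc,
        p_value=pvalue_from_pc(pc, n, k),
        n=n,
        df=n - 2 - k,
        controls=tuple(control_names),
    )


def fisher_interval(pc: float, n: int, k: int = 1, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a partial correlation.

    arctanh(pc) is approximately normal with se = 1/√(n − k − 3); the
    interval is transformed back with tanh.  Used for planted-effect
    recovery checks.
    """
    if n - k - 3 <= 0:
        raise SampleSizeError(f"need n - k - 3 > 0 (n={n}, k={k})")
    z = np.arctanh(np.clip(pc, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.5 + conf / 2) / np.sqrt(n - k - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlation_table(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    controls: pd.DataFrame | pd.Series | None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Partial-correlation table: one row per (target, feature) pair.

    ``features``, ``targets`` and ``controls`` are aligned DataFrames (rows
    = subjects).  Degenerate cells (constant variable, too few cases) are
    annotated in the ``note`` column rather than aborting the table; their
    pc and p are NaN.  Row order follows input column order, so tables are
    deterministic.

    With ``fdr=True`` a Benjamini–Hochberg adjusted p column ``p_fdr`` is
    appended (off by default: the flags always refer to the uncorrected
    bilateral thresholds).
    """
    if controls is None:
        Z, control_names = None, ()
    else:
        if isinstance(controls, pd.Series):
            controls = controls.to_frame()
        Z = controls.to_numpy(dtype=float)
        control_names = tuple(controls.columns)

    rows = []
    for tname in targets.columns:
        for fname in features.columns:
            cell = {
                "target": tname,
                "feature": fname,
                "pc": np.nan,
                "p_value": np.nan,
                "n": np.nan,
                "df": np.nan,
                "sig_05": False,
                "sig_01": False,
                "note": "",
            }
            try:
                res = partial_corr(
                    targets[tname].to_numpy(dtype=float),
                    features[fname].to_numpy(dtype=float),
                    Z,
                    control_names=control_names,
                )
                cell.update(
                    pc=res.pc,
                    p_value=res.p_value,
                    n=res.n,
                    df=res.df,
                    sig_05=res.sig_05,
                    sig_01=res.sig_01,
                )
            except (DegenerateInputError, SampleSizeError) as exc:
                cell["note"] = str(exc)
            rows.append(cell)
    table = pd.DataFrame(rows)
    if fdr:
        table["p_fdr"] = _bh_adjust(table["p_value"].to_numpy())
    return table


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return out
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def format_report(table: pd.DataFrame, title: str = "") -> str:
    """Human-readable paired-row report: one PC row and one p-value row per
    target, features as columns; significant p-values are starred
    (* p<0.05, ** p<0.01)."""
    lines = []
    if title:
        lines.append(title)
    feats = list(dict.fromkeys(table["feature"]))
    header = "\t".join([""] * 2 + feats)
    lines.append(header)
    for tname in dict.fromkeys(table["target"]):
        sub = table[table["target"] == tname].set_index("feature")
        pc_cells, p_cells = [], []
        for f in feats:
            if f not in sub.index or not np.isfinite(sub.loc[f, "pc"]):
                pc_cells.append("--")
                p_cells.append("--")
                continue
            pc_cells.append(f"{sub.loc[f, 'pc']:.3f}")
            p = sub.loc[f, "p_value"]
            star = "**" if sub.loc[f, "sig_01"] else ("*" if sub.loc[f, "sig_05"] else "")
            p_cells.append(f"{p:.3f}{star}")
        lines.append("\t".join([tname, "PC"] + pc_cells))
        lines.append("\t".join(["", "p-value"] + p_cells))
    return "\n".join(lines) + "\n"
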