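"""Discriminant reporting: VIP ranking, bin annotation against a chemical
shift table, direction-of-change tables, and univariate group statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multivariate import OplsModel, vip
from .processing import BinnedMatrix
from .templates import default_metabolite_library

__all__ = [
    "ShiftTable",
    "UnivariateResult",
    "default_shift_table",
    "rank_bins",
    "annotate",
    "direction_of_change",
    "univariate_test",
    "build_discriminant_table",
    "stars",
]

PPM_MIN, PPM_MAX = -0.5, 10.0


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ShiftTable:
    """Metabolite -> ppm interval lookup used for bin annotation.

    A bin may intersect several metabolites' intervals; annotation keeps
    the ambiguity (joined with '/')."""

    table: pd.DataFrame  # metabolite, ppm_lo, ppm_hi, note

    def __post_init__(self) -> None:
        required = {"metabolite", "ppm_lo", "ppm_hi"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"shift table needs columns {sorted(required)}")
        bad = self.table[
            (self.table.ppm_lo < PPM_MIN) | (self.table.ppm_hi > PPM_MAX)
        ]
        if len(bad):
            raise ValueError("shift-table interval outside the ppm range")

    @classmethod
    def from_csv(cls, path) -> "ShiftTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_shift_table(matrix: str) -> ShiftTable:
    """Shift table derived from the built-in metabolite templates, so
    annotations agree with the simulator's peak positions."""
    rows = []
    for template in default_metabolite_library(matrix):
        for lo, hi in template.support_intervals():
            rows.append(
                {
                    "metabolite": template.name,
                    "ppm_lo": round(lo, 4),
                    "ppm_hi": round(hi, 4),
                    "note": "library template",
                }
            )
    return ShiftTable(pd.DataFrame(rows))


def _parse_bin_label(label: str) -> tuple[float, float]:
    lo, hi = label[1:].split("_")
    return float(lo), float(hi)


def rank_bins(
    vip_scores: np.ndarray, bin_labels: list[str], threshold: float = 1.0
) -> list[tuple[str, float]]:
    """Bins with VIP strictly above ``threshold``, sorted descending."""
    vip_scores = np.asarray(vip_scores, dtype=float)
    if vip_scores.size != len(bin_labels):
        raise ValueError("one VIP score per bin label required")
    picked = [
        (lab, float(v)) for lab, v in zip(bin_labels, vip_scores) if v > threshold
    ]
    picked.sort(key=lambda kv: -kv[1])
    return picked


def annotate(bin_labels: list[str], table: ShiftTable) -> dict[str, str]:
    """Map each bin to every metabolite whose interval intersects it.

    Multi-hit bins join names with '/'; unmatched bins get 'unassigned'.
    """
    out = {}
    for lab in bin_labels:
        blo, bhi = _parse_bin_label(lab)
        hits = []
        for _, row in table.table.iterrows():
            if blo < row.ppm_hi and bhi > row.ppm_lo and row.metabolite not in hits:
                hits.append(row.metabolite)
        out[lab] = "/".join(hits) if hits else "unassigned"
    return out


@dataclass
class UnivariateResult:
    t: float
    df: float
    p: float
    mean_difference: float
    ci_low: float
    ci_high: float
    cohens_d: float
    levene_p: float
    equal_variances: bool
    transform: str  # none | sqrt


def univariate_test(values_a, values_b, sqrt_transform: bool = False) -> UnivariateResult:
    """Independent-samples t-test with the Levene decision rule.

    Levene's test (center=mean) at alpha 0.05 picks pooled vs Welch
    variants; Cohen's d always uses the pooled SD on the analyzed
    (possibly sqrt-transformed) scale.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if sqrt_transform:
        if (a < 0).any() or (b < 0).any():
            raise ValueError("sqrt transform requires non-negative values")
        a, b = np.sqrt(a), np.sqrt(b)

    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        levene_p = 1.0
    else:
        levene_p = float(stats.levene(a, b, center="mean").pvalue)
    equal_var = levene_p >= 0.05

    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if equal_var:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        df = float(
            (va / na + vb / nb) ** 2
            / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        )
    if se == 0:
        t_stat, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    else:
        t_stat = diff / se
        p = float(2 * stats.t.sf(abs(t_stat), df))
    crit = float(stats.t.ppf(0.975, df)) if np.isfinite(df) else np.nan
    ci_low = diff - crit * se
    ci_high = diff + crit * se
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = diff / sp if sp > 0 else 0.0
    return UnivariateResult(
        t=float(t_stat),
        df=df,
        p=p,
        mean_difference=diff,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        cohens_d=float(d),
        levene_p=levene_p,
        equal_variances=equal_var,
        transform="sqrt" if sqrt_transform else "none",
    )


def direction_of_change(
    m: BinnedMatrix,
    bins: list[str],
    positive_label: str,
    y=None,
) -> pd.DataFrame:
    """Per-bin direction of change (treated vs control) with t-test stats.

    Direction is up-arrow when the treated-group mean exceeds the control
    mean on the (normalized) bin values, down-arrow otherwise; ties with
    zero variance in both groups are flagged undefined.
    """
    groups = np.asarray(m.groups if y is None else y)
    classes = sorted(set(groups.tolist()), key=str)
    if positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not in groups {classes}")
    labels = m.bin_labels
    rows = []
    for bin_label in bins:
        j = labels.index(bin_label)
        col = m.values[:, j]
        treated = col[groups == positive_label]
        control = col[groups != positive_label]
        if treated.std(ddof=1) == 0 and control.std(ddof=1) == 0 and treated.mean() == control.mean():
            rows.append(
                {
                    "bin": bin_label,
                    "direction": "undefined",
                    "p": np.nan,
                    "stars": "",
                    "t": np.nan,
                    "df": np.nan,
                    "cohens_d": np.nan,
                }
            )
            continue
        res = univariate_test(treated, control)
        rows.append(
            {
                "bin": bin_label,
                "direction": "↑" if treated.mean() > control.mean() else "↓",
                "p": res.p,
                "stars": stars(res.p),
                "t": res.t,
                "df": res.df,
                "cohens_d": res.cohens_d,
            }
        )
    return pd.DataFrame(rows)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    # Benjamini-Hochberg; emitted as a clearly-labeled extension column
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def build_discriminant_table(
    m: BinnedMatrix,
    model: OplsModel,
    shift_table: ShiftTable | None = None,
    vip_threshold: float = 1.0,
    y=None,
) -> pd.DataFrame:
    """Full report table: VIP-ranked bins with annotation, direction,
    p-value and stars, sorted by VIP descending.

    p-values are NOT multiplicity-adjusted (a BH column is added as a
    labeled extension).
    """
    if shift_table is None:
        shift_table = default_shift_table(m.matrix)
    vip_scores = vip(model)
    bin_labels = model.feature_names or m.retained_labels()
    ranked = rank_bins(vip_scores, bin_labels, threshold=vip_threshold)
    if not ranked:
        return pd.DataFrame(
            columns=["bin", "vip", "annotation", "direction", "p", "stars", "p_bh_extension"]
        )
    names = [lab for lab, _ in ranked]
    ann = annotate(names, shift_table)
    doc = direction_of_change(m, names, positive_label=model.labels[1], y=y)
    doc = doc.set_index("bin")
    out = pd.DataFrame(
        {
            "bin": names,
            "vip": [v for _, v in ranked],
            "annotation": [ann[lab] for lab in names],
            "direction": doc.loc[names, "direction"].values,
            "p": doc.loc[names, "p"].values,
            "stars": doc.loc[names, "stars"].values,
        }
    )
    out["p_bh_extension"] = _bh_adjust(out["p"].values)
    return out
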