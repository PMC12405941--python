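"""Group statistics on tables of cell records.

Two-way ANOVA (species x eye region, Type-II sums of squares, no
interaction by default), Shapiro-Wilk normality of the residuals, Tukey
HSD pairwise comparisons with a compact letter display, and an OLS model
``fwhm_circ ~ ps + species + eye_region`` with treatment coding
(reference levels Apis / main_retina).

The input table is a pandas DataFrame with columns
``cell_id, species, eye_region, ps, fwhm_circ`` (``excluded`` optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError

ALPHA = 0.05
FACTORS = ("species", "eye_region")


@dataclass
class AnovaResult:
    response: str
    table: pd.DataFrame  # index: factor / Residual; cols: sum_sq, df, F, PR(>F)
    residuals: np.ndarray

    def to_dict(self) -> dict:
        out = {}
        for name, row in self.table.iterrows():
            out[str(name)] = {
                "sum_sq": float(row["sum_sq"]),
                "df": float(row["df"]),
                "F": None if np.isnan(row.get("F", np.nan)) else float(row["F"]),
                "p": None if np.isnan(row.get("PR(>F)", np.nan))
                else float(row["PR(>F)"]),
            }
        return {"response": self.response, "factors": out}


@dataclass
class TukeyResult:
    response: str
    group: str
    comparisons: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    letters: dict
    dropped_groups: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "group": self.group,
            "comparisons": self.comparisons.to_dict(orient="records"),
            "letters": self.letters,
            "dropped_groups": self.dropped_groups,
        }


def _check_table(df: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in FACTORS + (response,):
        if col not in df.columns:
            raise InputError(f"table lacks column {col!r}")
    sub = df.dropna(subset=[response, *FACTORS]).copy()
    for factor in FACTORS:
        if sub[factor].nunique() < 2:
            raise InputError(f"factor {factor!r} needs >= 2 levels with data")
    return sub


def two_way_anova(df: pd.DataFrame, response: str, *,
                  interaction: bool = False) -> AnovaResult:
    """Type-II two-way ANOVA of ``response`` on species and eye region."""
    sub = _check_table(df, response)
    rhs = "C(species) + C(eye_region)"
    if interaction:
        rhs += " + C(species):C(eye_region)"
    n_par = 1 + (sub["species"].nunique() - 1) + (sub["eye_region"].nunique() - 1)
    if interaction:
        n_par += (sub["species"].nunique() - 1) * (sub["eye_region"].nunique() - 1)
    if len(sub) <= n_par:
        raise InputError("not enough observations for residual degrees of freedom")
    fit = smf.ols(f"{response} ~ {rhs}", data=sub).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(index={
        "C(species)": "species",
        "C(eye_region)": "eye_region",
        "C(species):C(eye_region)": "species:eye_region",
    })
    return AnovaResult(response=response, table=table,
                       residuals=np.asarray(fit.resid))


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a residual vector (3 <= n <= 5000)."""
    x = np.asarray(residuals, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise InputError("Shapiro-Wilk requires a 1-D vector with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise InputError("residuals have zero variance")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def tukey_hsd(df: pd.DataFrame, response: str, group: str = "eye_region", *,
              alpha: float = ALPHA) -> TukeyResult:
    """Tukey HSD pairwise comparisons with compact letter display.

    Groups with fewer than 2 observations are dropped and reported in
    ``dropped_groups``.
    """
    if group not in df.columns or response not in df.columns:
        raise InputError(f"table lacks column {group!r} or {response!r}")
    sub = df.dropna(subset=[response, group]).copy()
    counts = sub.groupby(group)[response].count()
    dropped = sorted(counts[counts < 2].index.tolist())
    sub = sub[~sub[group].isin(dropped)]
    if sub[group].nunique() < 2:
        raise InputError("need >= 2 groups with >= 2 observations")
    res = pairwise_tukeyhsd(endog=sub[response].to_numpy(),
                            groups=sub[group].to_numpy(), alpha=alpha)
    pairs = list(combinations(res.groupsunique, 2))
    comp = pd.DataFrame({
        "group1": [a for a, _b in pairs],
        "group2": [b for _a, b in pairs],
        "meandiff": np.asarray(res.meandiffs, dtype=float),
        "p_adj": np.asarray(res.pvalues, dtype=float),
        "lower": np.asarray(res.confint[:, 0], dtype=float),
        "upper": np.asarray(res.confint[:, 1], dtype=float),
        "reject": np.asarray(res.reject, dtype=bool),
    })
    groups_sorted = sub.groupby(group)[response].mean().sort_values().index.tolist()
    sig_pairs = {
        frozenset((row["group1"], row["group2"]))
        for _, row in comp.iterrows() if row["reject"]
    }
    letters = _compact_letter_display(groups_sorted, sig_pairs)
    return TukeyResult(response=response, group=group, comparisons=comp,
                       letters=letters, dropped_groups=dropped)


def _compact_letter_display(groups: list, sig_pairs: set) -> dict:
    """Insert-and-absorb compact letter display.

    Starts from one letter covering every group; each significantly
    different pair splits any letter set containing both; duplicate or
    subset letter sets are absorbed.
    """
    sets: list[set] = [set(groups)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets / duplicates
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def fit_fwhm_ps_model(df: pd.DataFrame, *,
                      species_ref: str = "Apis",
                      region_ref: str = "main_retina") -> pd.DataFrame:
    """OLS of circular FWHM on PS with species and eye-region terms.

    Treatment coding with reference levels (Apis, main_retina).  Returns a
    coefficient table (estimate, se, t, p).
    """
    cols = ["fwhm_circ", "ps", "species", "eye_region"]
    for col in cols:
        if col not in df.columns:
            raise InputError(f"table lacks column {col!r}")
    sub = df.dropna(subset=cols).copy()
    if len(sub) < 5:
        raise InputError("need >= 5 complete cases")
    if species_ref not in set(sub["species"]):
        raise InputError(f"reference species level {species_ref!r} absent")
    if region_ref not in set(sub["eye_region"]):
        raise InputError(f"reference eye-region level {region_ref!r} absent")
    formula = (
        f"fwhm_circ ~ ps + C(species, Treatment('{species_ref}'))"
        f" + C(eye_region, Treatment('{region_ref}'))"
    )
    fit = smf.ols(formula, data=sub).fit()
    X = fit.model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate offending columns by incremental rank
        names = fit.model.exog_names
        bad = []
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j - len(bad):
                bad.append(names[j - 1])
        raise InputError(f"design matrix is rank deficient; collinear: {bad}")
    table = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    table.index = [_clean_term(t, species_ref, region_ref) for t in table.index]
    return table


def _clean_term(term: str, species_ref: str, region_ref: str) -> str:
    term = term.replace(f"C(species, Treatment('{species_ref}'))[T.", "species[")
    term = term.replace(f"C(eye_region, Treatment('{region_ref}'))[T.", "eye_region[")
    return term


def stats_report(df: pd.DataFrame) -> dict:
    """Full statistics block: ANOVAs on PS and FWHM with residual normality,
    Tukey HSD per response over eye regions, and the FWHM ~ PS model."""
    report: dict = {}
    for response in ("ps", "fwhm_circ"):
        try:
            an = two_way_anova(df, response)
            w, p = shapiro_wilk(an.residuals)
            tk = tukey_hsd(df, response)
            report[response] = {
                "anova": an.to_dict(),
                "shapiro": {"W": w, "p": p},
                "tukey": tk.to_dict(),
            }
        except InputError as exc:
            report[response] = {"error": str(exc)}
    try:
        lm = fit_fwhm_ps_model(df)
        report["fwhm_ps_model"] = {
            name: {"estimate": float(row["estimate"]), "se": float(row["se"]),
                   "p": float(row["p"])}
            for name, row in lm.iterrows()
        }
    except InputError as exc:
        report["fwhm_ps_model"] = {"error": str(exc)}
    return report
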