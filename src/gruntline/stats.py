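"""Mixed-effects models, Wald ANOVA tables and Tukey-adjusted contrasts.

Each response (behavioural scores, acoustic score, log grunt duration, mean
inter-grunt interval, door-occupancy time) is modelled with a linear mixed
model with a random intercept per piglet (REML).  Factors are coded with
sum-to-zero contrasts, so the per-term Wald chi-square tests reported by
:func:`anova_wald` match the conventional Type-II car-style ANOVA in the
balanced designs this package generates.

Post-hoc comparisons are estimated marginal means over a factor grid with
all pairwise differences adjusted by the Tukey (studentized-range) method;
degrees of freedom are large-sample (no small-sample correction — with ~60
subjects the difference is negligible).
"""
from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats as sps

from . import ethogram, features as feat, scoring, segmentation
from .synthetic_data import TRIAL_BLOCKS, StudyDataset

__all__ = [
    "ModelFit",
    "fit_lmm",
    "anova_wald",
    "tukey_contrasts",
    "estimated_marginal_means",
    "score_model_formula",
    "igi_model_formula",
    "door_model_formula",
    "run_full_analysis",
    "sign_pattern_holds",
    "ResultsBundle",
]


def _c(v: str) -> str:
    return f"C({v}, Sum)"


def score_model_formula(response: str) -> str:
    """Full design model: two-way interactions among phase, partner and
    treatment, plus replicate × partner and replicate × treatment."""
    p, q, t, r = map(_c, ("phase", "partner", "treatment", "replicate"))
    return f"{response} ~ {p}*{q} + {p}*{t} + {q}*{t} + {r}*{q} + {r}*{t}"


def igi_model_formula(response: str = "mean_igi") -> str:
    """Anticipation-phase-only rhythm model (no phase factor)."""
    q, t, r = map(_c, ("partner", "treatment", "replicate"))
    return f"{response} ~ {q}*{t} + {r}*{q} + {r}*{t}"


def door_model_formula(response: str = "near_door_time") -> str:
    """Door-preference model over conditioning trial blocks."""
    b, q, t, r = map(_c, ("trial_block", "partner", "treatment", "replicate"))
    return f"{response} ~ {b}*{q}*{t} + {r}*{q} + {r}*{t}"


_FACTOR_RE = re.compile(r"C\((\w+)")


@dataclass
class ModelFit:
    """A fitted mixed model plus the bookkeeping needed for ANOVA and EMMs."""

    result: object                 # statsmodels MixedLMResults
    formula: str
    data: pd.DataFrame
    design_info: object            # patsy DesignInfo of the fixed effects
    factor_levels: dict[str, list]
    converged: bool

    @property
    def fe_names(self) -> list[str]:
        return list(self.design_info.column_names)

    def fixed_cov(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    def residual_table(self) -> pd.DataFrame:
        """Fitted values, residuals and random effects, for diagnostics."""
        out = self.data.copy()
        out["fitted"] = np.asarray(self.result.fittedvalues)
        out["residual"] = np.asarray(self.result.resid)
        return out


def _check_aliasing(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, rmat = np.linalg.qr(exog)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * 1e-10
        aliased = [names[i] for i in np.flatnonzero(diag < tol)]
        raise ValueError(f"singular fixed-effect design; aliased columns: {aliased}")


def fit_lmm(
    formula: str,
    data: pd.DataFrame,
    groups: str = "piglet",
    reml: bool = True,
) -> ModelFit:
    """Fit a linear mixed model with a random intercept per ``groups``.

    Raises on singular (aliased) fixed-effect designs and on fits that end
    with non-finite estimates; boundary fits (zero random-effect variance)
    are returned with ``converged`` reflecting the optimizer's verdict.
    """
    resp = formula.split("~")[0].strip()
    if data[resp].isna().any():
        raise ValueError(f"response {resp!r} contains missing values")
    if data[groups].nunique() < 2:
        raise ValueError("random grouping needs at least 2 levels")
    model = smf.mixedlm(formula, data, groups=data[groups])
    _check_aliasing(model.exog, list(model.exog_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    if not np.all(np.isfinite(result.fe_params)):
        raise RuntimeError(
            f"mixed-model optimization failed for {formula!r}: "
            f"non-finite estimates ({result.mle_retvals})"
        )
    factors = sorted(set(_FACTOR_RE.findall(formula)))
    levels = {f: sorted(pd.unique(data[f]).tolist()) for f in factors}
    return ModelFit(
        result=result,
        formula=formula,
        data=data,
        design_info=model.data.design_info,
        factor_levels=levels,
        converged=bool(result.converged),
    )


def anova_wald(fit: ModelFit) -> pd.DataFrame:
    """Per-term Wald chi-square table for the fixed effects.

    Tests each term's coefficients jointly against zero using the REML
    covariance; with sum-to-zero coding this reproduces the reporting style
    "X²(df) = …, p = …" of car-style mixed-model ANOVAs.
    """
    beta = np.asarray(fit.result.fe_params)
    V = fit.fixed_cov()
    rows = []
    for term, sl in fit.design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = beta[sl]
        Vb = V[sl, sl]
        stat = float(b @ np.linalg.solve(Vb, b))
        df = b.size
        rows.append(
            {
                "term": term.replace("C(", "").replace(", Sum)", ""),
                "statistic": stat,
                "df": df,
                "p": float(sps.chi2.sf(stat, df)),
            }
        )
    return pd.DataFrame(rows)


def _emm_design(fit: ModelFit, factors: list[str]) -> tuple[list[tuple], np.ndarray]:
    """Cells of the family grid and their EMM contrast rows.

    The EMM of a cell is the model prediction averaged over a balanced grid
    of the remaining factors.
    """
    for f in factors:
        if f not in fit.factor_levels:
            raise ValueError(f"{f!r} is not a factor of this model")
    all_factors = list(fit.factor_levels)
    grid = pd.DataFrame(
        list(product(*[fit.factor_levels[f] for f in all_factors])),
        columns=all_factors,
    )
    (X,) = patsy.build_design_matrices([fit.design_info], grid)
    X = np.asarray(X)
    cells = list(product(*[fit.factor_levels[f] for f in factors]))
    rows = []
    for cell in cells:
        mask = np.ones(len(grid), dtype=bool)
        for f, lev in zip(factors, cell):
            mask &= (grid[f] == lev).to_numpy()
        if not mask.any():
            raise ValueError(f"empty cell {dict(zip(factors, cell))}")
        # also require observed data in the cell
        dmask = np.ones(len(fit.data), dtype=bool)
        for f, lev in zip(factors, cell):
            dmask &= (fit.data[f] == lev).to_numpy()
        if not dmask.any():
            raise ValueError(f"no data in cell {dict(zip(factors, cell))}")
        rows.append(X[mask].mean(axis=0))
    return cells, np.asarray(rows)


def estimated_marginal_means(fit: ModelFit, factors: list[str]) -> pd.DataFrame:
    """Estimated marginal means over the grid of ``factors``."""
    cells, L = _emm_design(fit, factors)
    beta = np.asarray(fit.result.fe_params)
    V = fit.fixed_cov()
    est = L @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, V, L))
    out = pd.DataFrame(cells, columns=factors)
    out["emmean"] = est
    out["se"] = se
    return out


def tukey_contrasts(fit: ModelFit, factors: list[str]) -> pd.DataFrame:
    """All pairwise EMM differences within a factor family, Tukey-adjusted.

    ``T.ratio`` is estimate / SE; the adjusted p uses the studentized-range
    distribution with the family size as the number of means, on
    large-sample degrees of freedom.
    """
    cells, L = _emm_design(fit, factors)
    beta = np.asarray(fit.result.fe_params)
    V = fit.fixed_cov()
    k = len(cells)
    df = max(int(fit.result.nobs) - len(beta), 10)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(cells), 2):
        l = L[i] - L[j]
        est = float(l @ beta)
        se = float(np.sqrt(l @ V @ l))
        t = est / se if se > 0 else 0.0
        p_unadj = float(2.0 * sps.t.sf(abs(t), df))
        bonf = k * (k - 1) / 2.0 * p_unadj
        if bonf < 1e-10:
            # Tukey p is sandwiched between p_unadj and its Bonferroni bound;
            # at this magnitude the slow studentized-range quadrature adds
            # nothing beyond "vanishingly small"
            p_adj = bonf
        else:
            p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        rows.append(
            {
                "contrast": f"{_cell_name(factors, a)} - {_cell_name(factors, b)}",
                **{f"{f}_1": a[m] for m, f in enumerate(factors)},
                **{f"{f}_2": b[m] for m, f in enumerate(factors)},
                "estimate": est,
                "se": se,
                "T.ratio": t,
                "df": df,
                "p_tukey": min(p_adj, 1.0),
                "p_unadj": min(p_unadj, 1.0),
            }
        )
    return pd.DataFrame(rows)


def _cell_name(factors: list[str], cell: tuple) -> str:
    return ",".join(f"{f}={v}" for f, v in zip(factors, cell))


def _find_contrast(
    contrasts: pd.DataFrame, factors: list[str], cell_a: tuple, cell_b: tuple
) -> pd.Series:
    """The (possibly sign-flipped) contrast row between two cells."""
    for sign, (x, y) in (((1.0), (cell_a, cell_b)), ((-1.0), (cell_b, cell_a))):
        mask = np.ones(len(contrasts), dtype=bool)
        for m, f in enumerate(factors):
            mask &= (contrasts[f"{f}_1"] == x[m]) & (contrasts[f"{f}_2"] == y[m])
        if mask.any():
            row = contrasts[mask].iloc[0].copy()
            row["estimate"] *= sign
            row["T.ratio"] *= sign
            return row
    raise KeyError(f"contrast {cell_a} vs {cell_b} not in table")


# ---------------------------------------------------------------------------
# full analysis recipe

BEHAVIOUR_LDA_VARIABLES = list(ethogram.BEHAVIOUR_VARIABLES)
ACOUSTIC_LDA_VARIABLES = list(feat.ACOUSTIC_SCORE_VARIABLES)


@dataclass
class ResultsBundle:
    """Everything the analysis produces, in machine-readable form."""

    features: pd.DataFrame
    behaviour_records: pd.DataFrame
    behaviour_model: scoring.ScoreModel
    acoustic_model: scoring.ScoreModel
    behaviour_scores: pd.DataFrame
    grunt_scores: pd.DataFrame
    igi: pd.DataFrame
    anovas: dict[str, pd.DataFrame]
    contrasts: dict[str, pd.DataFrame]
    diffspec: pd.DataFrame
    sign_pattern: dict
    residuals: dict[str, pd.DataFrame]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(outdir / "features.csv", index=False)
        self.behaviour_records.to_csv(outdir / "behaviour_records.csv", index=False)
        self.behaviour_model.loadings_table().to_csv(outdir / "loadings_behaviour.csv")
        self.acoustic_model.loadings_table().to_csv(outdir / "loadings_acoustic.csv")
        self.behaviour_scores.to_csv(outdir / "scores_behaviour.csv", index=False)
        self.grunt_scores.to_csv(outdir / "scores_acoustic.csv", index=False)
        self.igi.to_csv(outdir / "igi.csv", index=False)
        self.diffspec.to_csv(outdir / "diffspec.csv", index=False)
        for name, table in self.anovas.items():
            table.to_csv(outdir / f"anova_{name}.csv", index=False)
        for name, table in self.contrasts.items():
            table.to_csv(outdir / f"contrasts_{name}.csv", index=False)
        for name, table in self.residuals.items():
            table.to_csv(outdir / f"residuals_{name}.csv", index=False)
        (outdir / "results_summary.json").write_text(
            json.dumps(self.sign_pattern, indent=2, default=float)
        )


def _score_response_models(
    data: pd.DataFrame, response: str, anovas: dict, contrasts: dict, residuals: dict
) -> ModelFit:
    fit = fit_lmm(score_model_formula(response), data)
    anovas[response] = anova_wald(fit)
    contrasts[f"{response}_phase_partner"] = tukey_contrasts(fit, ["phase", "partner"])
    contrasts[f"{response}_partner_treatment"] = tukey_contrasts(
        fit, ["partner", "treatment"]
    )
    residuals[response] = fit.residual_table()
    return fit


def _anova_p(anova: pd.DataFrame, term: str) -> float:
    row = anova[anova["term"] == term]
    if row.empty:
        raise KeyError(f"term {term!r} not in ANOVA table")
    return float(row.iloc[0]["p"])


def run_full_analysis(
    dataset: StudyDataset, alpha: float = 0.05, pad: float = 0.05
) -> ResultsBundle:
    """Run the complete pipeline on one study dataset.

    Acoustic route: render each annotated grunt, band-pass, refine its
    boundaries by the 5 % amplitude threshold, measure the spectro-temporal
    descriptors; fit the acoustic discriminant on phases −1/0 and project
    the delayed phases.  Behavioural route: per-minute ethogram variables,
    behavioural discriminant and projection.  Then the mixed-model recipes:
    one per score and for log duration, the anticipation-phase rhythm model,
    and the door-preference trial-block model, each with Wald ANOVA and
    Tukey contrasts.  Between-partner mean-spectrum dissimilarity D is
    computed per phase, and a machine-readable sign-pattern block summarises
    the headline effect directions.
    """
    anovas: dict[str, pd.DataFrame] = {}
    contrasts: dict[str, pd.DataFrame] = {}
    residuals: dict[str, pd.DataFrame] = {}

    # ---- acoustic features -------------------------------------------------
    features, spectra, freqs = feat.extract_feature_table(dataset, pad=pad)

    train_mask = features["phase"].isin([-1, 0])
    labels = scoring.make_group_factor(
        features.loc[train_mask, "phase"].to_numpy(),
        features.loc[train_mask, "treatment"].to_numpy(),
        features.loc[train_mask, "partner"].to_numpy(),
    )
    acoustic_model = scoring.fit_lda(
        features.loc[train_mask],
        labels,
        n_axes=1,
        variables=ACOUSTIC_LDA_VARIABLES,
        anchors=[("entropy_h", -1)],
    )
    grunt_scores = features.copy()
    grunt_scores["LD1ac"] = scoring.project(acoustic_model, features)["LD1"]
    grunt_scores["log_duration"] = features["log_duration"]

    # ---- behaviour ---------------------------------------------------------
    behaviour_records = ethogram.standardize_behaviours(
        dataset.behaviour, dataset.phases
    )
    analysed = behaviour_records["trial"].isin(dataset.design.trials_analysed)
    brec = behaviour_records[analysed].reset_index(drop=True)
    btrain = brec["phase"].isin([-1, 0])
    blabels = scoring.make_group_factor(
        brec.loc[btrain, "phase"].to_numpy(),
        brec.loc[btrain, "treatment"].to_numpy(),
        brec.loc[btrain, "partner"].to_numpy(),
    )
    behaviour_model = scoring.fit_lda(
        brec.loc[btrain],
        blabels,
        n_axes=2,
        variables=BEHAVIOUR_LDA_VARIABLES,
        anchors=[("near_door_time", -1), ("near_door_time", -1)],
    )
    bscores = scoring.project(behaviour_model, brec)
    behaviour_scores = brec.copy()
    behaviour_scores["LD1bev"] = bscores["LD1"]
    behaviour_scores["LD2bev"] = bscores["LD2"]

    # ---- mixed models on scores -------------------------------------------
    fits: dict[str, ModelFit] = {}
    for resp in ("LD1bev", "LD2bev"):
        fits[resp] = _score_response_models(
            behaviour_scores, resp, anovas, contrasts, residuals
        )
    for resp in ("LD1ac", "log_duration"):
        fits[resp] = _score_response_models(
            grunt_scores, resp, anovas, contrasts, residuals
        )

    # ---- rhythm model (anticipation phase only) ----------------------------
    igi = segmentation.rhythm_table(
        features.assign(type="grunt"), onset_col="onset_s"
    )
    igi = igi[(igi["phase"] == 0) & (igi["n_grunts"] >= 2)].reset_index(drop=True)
    igi = igi.merge(
        dataset.phases[
            ["piglet", "trial", "phase", "partner", "treatment", "replicate"]
        ],
        on=["piglet", "trial", "phase"],
        how="left",
    )
    fits["mean_igi"] = fit_lmm(igi_model_formula(), igi)
    anovas["mean_igi"] = anova_wald(fits["mean_igi"])
    contrasts["mean_igi_partner"] = tukey_contrasts(fits["mean_igi"], ["partner"])
    residuals["mean_igi"] = fits["mean_igi"].residual_table()

    # ---- door-preference trial-block model ---------------------------------
    door = behaviour_records[behaviour_records["phase"] == -1].reset_index(drop=True)
    fits["door"] = fit_lmm(door_model_formula(), door)
    anovas["door"] = anova_wald(fits["door"])
    contrasts["door_block_partner"] = tukey_contrasts(
        fits["door"], ["trial_block", "partner"]
    )
    residuals["door"] = fits["door"].residual_table()

    # ---- spectral dissimilarity between partners, per phase ----------------
    drows = []
    for phase in sorted(features["phase"].unique()):
        specs = {}
        for partner in ("C", "H"):
            mask = (
                (features["phase"] == phase) & (features["partner"] == partner)
            ).to_numpy()
            if not mask.any():
                continue
            mean_amp = spectra[mask].mean(axis=0)
            specs[partner] = feat.MeanSpectrum(freqs, mean_amp / mean_amp.sum())
        if len(specs) == 2:
            drows.append(
                {
                    "phase": phase,
                    "D": feat.spectral_dissimilarity(specs["C"], specs["H"]),
                }
            )
    diffspec = pd.DataFrame(drows)

    # ---- sign-pattern summary ----------------------------------------------
    cpp = contrasts["log_duration_phase_partner"]
    igi_emm = estimated_marginal_means(fits["mean_igi"], ["partner"])
    igi_diff = float(
        igi_emm.loc[igi_emm.partner == "C", "emmean"].iloc[0]
        - igi_emm.loc[igi_emm.partner == "H", "emmean"].iloc[0]
    )
    dur_h = _find_contrast(cpp, ["phase", "partner"], (0, "H"), (-1, "H"))
    delayed = [
        _find_contrast(cpp, ["phase", "partner"], (p, "C"), (0, "C")) for p in (1, 2, 3)
    ]
    ld = contrasts["LD1ac_phase_partner"]
    ld_by_phase = {
        p: _find_contrast(ld, ["phase", "partner"], (p, "C"), (p, "H"))
        for p in (-1, 0, 1, 2, 3)
    }
    sign_pattern = {
        "alpha": alpha,
        "igi_c_minus_h_phase0": igi_diff,
        "igi_partner_p": _anova_p(anovas["mean_igi"], "partner"),
        "duration_h_phase0_minus_m1": float(dur_h["estimate"]),
        "duration_h_phase0_minus_m1_p": float(dur_h["p_tukey"]),
        "duration_c_delayed_minus_phase0": [float(r["estimate"]) for r in delayed],
        "duration_c_delayed_minus_phase0_p": [float(r["p_tukey"]) for r in delayed],
        "ld1ac_partner_p_by_phase": {
            str(p): float(r["p_tukey"]) for p, r in ld_by_phase.items()
        },
        "duration_phase_partner_p": _anova_p(anovas["log_duration"], "phase:partner"),
        "ld1ac_phase_partner_p": _anova_p(anovas["LD1ac"], "phase:partner"),
        "duration_partner_treatment_p": _anova_p(
            anovas["log_duration"], "partner:treatment"
        ),
        "n_grunts": int(len(features)),
        "diffspec": {str(int(r.phase)): float(r.D) for r in diffspec.itertuples()},
    }

    return ResultsBundle(
        features=features,
        behaviour_records=behaviour_records,
        behaviour_model=behaviour_model,
        acoustic_model=acoustic_model,
        behaviour_scores=behaviour_scores,
        grunt_scores=grunt_scores,
        igi=igi,
        anovas=anovas,
        contrasts=contrasts,
        diffspec=diffspec,
        sign_pattern=sign_pattern,
        residuals=residuals,
    )


def sign_pattern_holds(sign_pattern: dict, alpha: float = 0.05) -> bool:
    """Whether one analysis reproduces the expected direction pattern.

    Checks: faster grunting (shorter IGI) anticipating conspecifics; longer
    grunts anticipating the human; longer grunts on conspecific trials once
    the partner is delayed; the acoustic-score partner divergence confined
    to the anticipation phase; and significant phase × partner interactions
    for duration and the acoustic score.
    """
    sp = sign_pattern
    ld_p = sp["ld1ac_partner_p_by_phase"]
    return bool(
        sp["igi_c_minus_h_phase0"] < 0
        and sp["igi_partner_p"] < alpha
        and sp["duration_h_phase0_minus_m1"] > 0
        and sp["duration_h_phase0_minus_m1_p"] < alpha
        and all(e > 0 for e in sp["duration_c_delayed_minus_phase0"])
        and all(p < alpha for p in sp["duration_c_delayed_minus_phase0_p"])
        and ld_p["0"] < alpha
        and all(ld_p[str(p)] >= alpha for p in (-1, 1, 2, 3))
        and sp["duration_phase_partner_p"] < alpha
        and sp["ld1ac_phase_partner_p"] < alpha
    )
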