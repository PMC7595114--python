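"""Discriminant score construction and held-out projection.

The behavioural and acoustic spaces are summarised by Fisher linear
discriminant axes fitted on the pre-stimulus and stimulus phases only
(phases −1 and 0), discriminating the crossed groups of an ad hoc
phase × treatment × partner factor.  Delayed phases (1–3) are never refit:
they are scored by projecting onto the stored axes.

Variables are centred on their grand mean and scaled by the pooled
within-group standard deviation before axis extraction, so loadings are
comparable across variables.  A small ridge on the within-group covariance
(1e-8 × its mean diagonal) makes the fit deterministic under exact
collinearity — required because the nine acoustic inputs contain an exact
duplicate (mean = centroid).

Axis signs are fixed by anchors (variable, required sign) so reported
loading signs are reproducible across resamplings.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = ["ScoreModel", "make_group_factor", "fit_lda", "project"]

TRAINING_PHASES = (-1, 0)


def make_group_factor(phase, treatment, partner):
    """Build the ad hoc phase × treatment × partner training label.

    Accepts scalars or aligned sequences.  Only the two training phases
    (−1 and 0) are legal: delayed phases must never enter the fit.
    """
    phase_arr = np.atleast_1d(np.asarray(phase))
    if not np.isin(phase_arr, TRAINING_PHASES).all():
        bad = sorted(set(phase_arr[~np.isin(phase_arr, TRAINING_PHASES)].tolist()))
        raise ValueError(
            f"phase(s) {bad} are not training phases; the score model is fit "
            f"on phases {TRAINING_PHASES} only"
        )
    treat_arr = np.atleast_1d(np.asarray(treatment, dtype=object))
    part_arr = np.atleast_1d(np.asarray(partner, dtype=object))
    labels = np.array(
        [f"P{p}.{t}.{q}" for p, t, q in zip(phase_arr, treat_arr, part_arr)],
        dtype=object,
    )
    return labels[0] if np.isscalar(phase) else labels


@dataclass
class ScoreModel:
    """Fitted discriminant axes with their standardisation constants."""

    input_variables: list[str]
    classes: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray          # variables × axes, for standardised inputs
    eigenvalues: np.ndarray       # discriminant eigenvalues, decreasing
    axis_names: list[str]
    class_means: pd.DataFrame     # mean score per training group per axis

    def loadings_table(self) -> pd.DataFrame:
        """Loadings in the shape the score tables are reported in."""
        return pd.DataFrame(
            self.loadings, index=self.input_variables, columns=self.axis_names
        )


def _validate_table(table: pd.DataFrame, variables: list[str] | None) -> pd.DataFrame:
    if variables is None:
        variables = list(table.columns)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing input variable(s): {missing}")
    X = table[variables]
    if X.isna().any().any():
        raise ValueError("input table contains missing values")
    return X


def fit_lda(
    table: pd.DataFrame,
    labels,
    n_axes: int = 1,
    variables: list[str] | None = None,
    anchors: list[tuple[str, int]] | None = None,
    axis_prefix: str = "LD",
    ridge: float = 1e-8,
) -> ScoreModel:
    """Fit Fisher discriminant axes on a rows × variables table.

    ``anchors`` gives, per axis, a (variable, required sign) pair; with no
    anchor the largest-|loading| variable is made positive.  Every group must
    contribute at least two rows.
    """
    X = _validate_table(table, variables)
    variables = list(X.columns)
    labels = np.asarray(labels)
    if labels.shape[0] != len(X):
        raise ValueError("labels must align with table rows")
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than 2 rows: {list(small.index)}")

    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    k = len(classes)
    grand = Xv.mean(axis=0)

    # pooled within-group scatter
    Sw = np.zeros((p, p))
    means = {}
    for cls in classes:
        sub = Xv[labels == cls]
        m = sub.mean(axis=0)
        means[cls] = m
        d = sub - m
        Sw += d.T @ d
    Sw /= n - k

    scale = np.sqrt(np.diag(Sw))
    if np.any(scale <= 0):
        degenerate = [variables[i] for i in np.flatnonzero(scale <= 0)]
        raise ValueError(f"zero within-group variance for {degenerate}")
    Z = (Xv - grand) / scale
    Swz = np.zeros((p, p))
    Sbz = np.zeros((p, p))
    zmeans = {}
    for cls in classes:
        sub = Z[labels == cls]
        m = sub.mean(axis=0)
        zmeans[cls] = m
        d = sub - m
        Swz += d.T @ d
        Sbz += len(sub) * np.outer(m, m)
    Swz /= n - k
    Sbz /= k - 1
    Swz_reg = Swz + ridge * np.trace(Swz) / p * np.eye(p)

    eigvals, eigvecs = scipy.linalg.eigh(Sbz, Swz_reg)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(n_axes, k - 1, p)
    eigvals = eigvals[order][:n_axes]
    W = eigvecs[:, order][:, :n_axes]

    for a in range(n_axes):
        if anchors is not None and a < len(anchors):
            var, sign = anchors[a]
            if var not in variables:
                raise ValueError(f"anchor variable {var!r} not among inputs")
            val = W[variables.index(var), a]
        else:
            sign = 1
            val = W[np.argmax(np.abs(W[:, a])), a]
        if val * sign < 0:
            W[:, a] = -W[:, a]

    axis_names = [f"{axis_prefix}{a + 1}" for a in range(n_axes)]
    class_scores = pd.DataFrame(
        {cls: zmeans[cls] @ W for cls in classes}, index=axis_names
    ).T
    return ScoreModel(
        input_variables=variables,
        classes=classes,
        center=grand,
        scale=scale,
        loadings=W,
        eigenvalues=eigvals,
        axis_names=axis_names,
        class_means=class_scores,
    )


def project(model: ScoreModel, new_rows: pd.DataFrame) -> pd.DataFrame:
    """Score rows (training or held-out) with a fitted model.

    Scores are the standardised variables times the loadings; projecting the
    training table reproduces the fit-time scores exactly.
    """
    X = _validate_table(new_rows, model.input_variables)
    Z = (X.to_numpy(dtype=float) - model.center) / model.scale
    scores = Z @ model.loadings
    return pd.DataFrame(scores, columns=model.axis_names, index=new_rows.index)
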