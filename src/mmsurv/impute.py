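"""Data-level imputation comparators for the masked-attention mechanism.

Both fill every missing covariate and hence set all presence masks true
downstream, isolating the fusion mechanism as the only difference between
strategies.  MICE is chained conditional modelling (logistic for
categoricals, linear for continuous), 10 iterations, seed-controlled.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .tabular import CATEGORIES, PatientRecord

_COVARIATES = ("age", "sex", "kps", "who_grade", "histology", "idh",
               "codeletion_1p19q", "mgmtp", "eor", "radiotherapy",
               "chemotherapy")
_CONTINUOUS = ("age", "kps")


def _frame(records: list[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {v: [getattr(r, v) for r in records] for v in _COVARIATES}
    )
    for v in _CONTINUOUS:
        df[v] = pd.to_numeric(df[v], errors="coerce").astype(float)
    return df


def _rebuild(records, df) -> list[PatientRecord]:
    out = []
    for i, r in enumerate(records):
        kwargs = {}
        for v in _COVARIATES:
            val = df.at[i, v]
            if v == "age":
                kwargs[v] = float(val)
            elif v == "kps":
                kwargs[v] = int(round(float(val) / 10.0) * 10)
            else:
                kwargs[v] = str(val)
        out.append(replace(r, **kwargs))
    return out


def mode_impute(records: list[PatientRecord]) -> list[PatientRecord]:
    """Fill categoricals with the cohort mode, continuous with the median."""
    df = _frame(records)
    for v in _COVARIATES:
        if df[v].isna().all():
            raise ValueError(f"variable {v!r} entirely missing; cannot impute")
        if v in _CONTINUOUS:
            df[v] = df[v].fillna(df[v].median())
        else:
            df[v] = df[v].fillna(df[v].mode().iloc[0])
    return _rebuild(records, df)


def _design(df: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = []
    for v in _COVARIATES:
        if v == exclude:
            continue
        if v in _CONTINUOUS:
            x = df[v].astype(float).to_numpy()
            cols.append((x - x.mean()) / (x.std() + 1e-9))
        else:
            for cat in CATEGORIES[v]:
                cols.append((df[v] == cat).astype(float).to_numpy())
    return np.column_stack(cols)


def mice_impute(records: list[PatientRecord], n_iter: int = 10,
                seed: int = 0) -> list[PatientRecord]:
    """Multivariate imputation by chained equations with stochastic draws."""
    from sklearn.linear_model import LinearRegression, LogisticRegression

    rng = np.random.default_rng(seed)
    df = _frame(records)
    missing = {v: df[v].isna().to_numpy() for v in _COVARIATES}
    # initialize with mode/median
    init = _frame(mode_impute(records))
    df = init.copy()

    for _ in range(n_iter):
        for v in _COVARIATES:
            m = missing[v]
            if not m.any():
                continue
            X = _design(df, v)
            if v in _CONTINUOUS:
                model = LinearRegression().fit(X[~m], df.loc[~m, v].astype(float))
                pred = model.predict(X[m])
                resid = df.loc[~m, v].astype(float) - model.predict(X[~m])
                sd = float(np.std(resid)) or 1e-6
                df.loc[m, v] = pred + rng.normal(0, sd, size=m.sum())
                if v == "kps":
                    df.loc[m, v] = np.clip(
                        np.round(df.loc[m, v].astype(float) / 10) * 10, 30, 100
                    )
                else:
                    df.loc[m, v] = np.clip(df.loc[m, v].astype(float), 18, 90)
            else:
                y_obs = df.loc[~m, v].astype(str)
                if y_obs.nunique() < 2:
                    df.loc[m, v] = y_obs.iloc[0]
                    continue
                model = LogisticRegression(max_iter=200).fit(X[~m], y_obs)
                probs = model.predict_proba(X[m])
                classes = model.classes_
                draws = [classes[rng.choice(len(classes), p=p / p.sum())]
                         for p in probs]
                df.loc[m, v] = draws
    return _rebuild(records, df)
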