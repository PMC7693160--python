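"""Model-performance statistics and reporting.

Mean relative deviation of predicted concentrations,

    MRD = 10 ** sqrt( mean( (log10 Ci - log10 Ci_hat)^2 ) ),

geometric mean fold error of summary parameters,

    GMFE = 10 ** mean( |log10(a_hat_j / a_j)| ),

the prediction ratio R_pred/obs with two-fold (|log10 R| <= 0.301) and
1.25-fold (|log10 R| <= 0.097) classification, and the DDI exposure ratio
(victim AUC_last or Cmax with perpetrator / control).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ProfilePair", "StudySummary", "mrd", "gmfe", "rpred_obs",
           "classify", "ddi_ratio_eval", "report", "EvaluationReport",
           "LOG_1_25", "LOG_2"]

LOG_1_25 = 0.097
LOG_2 = 0.301


@dataclass
class ProfilePair:
    """Matched observed/predicted concentrations at common times."""

    observed: np.ndarray
    predicted: np.ndarray
    study: str = ""
    n_excluded: int = 0

    def __post_init__(self):
        obs = np.asarray(self.observed, float)
        pred = np.asarray(self.predicted, float)
        if obs.shape != pred.shape:
            raise ValueError("observed/predicted length mismatch")
        keep = (obs > 0) & (pred > 0)
        self.n_excluded = int((~keep).sum())
        self.observed, self.predicted = obs[keep], pred[keep]

    @classmethod
    def from_profiles(cls, t_obs, c_obs, t_pred, c_pred, study=""):
        """Align by linear interpolation of predictions onto observed
        times."""
        return cls(np.asarray(c_obs, float),
                   np.interp(t_obs, t_pred, c_pred), study)


@dataclass
class StudySummary:
    study: str
    observed: dict[str, float]     # parameter -> value
    predicted: dict[str, float]

    def ratios(self) -> dict[str, float]:
        return {k: self.predicted[k] / self.observed[k]
                for k in self.observed if k in self.predicted
                and self.observed[k] > 0}


def mrd(pair: ProfilePair) -> float:
    """Mean relative deviation (>= 1) of a matched profile pair."""
    if pair.observed.size == 0:
        raise ValueError("no positive concentration pairs")
    d = np.log10(pair.observed) - np.log10(pair.predicted)
    return float(10.0 ** np.sqrt(np.mean(d * d)))


def gmfe(summaries: list[StudySummary], parameter: str) -> float:
    """Geometric mean fold error (>= 1) of one summary parameter across
    studies."""
    logs = []
    for s in summaries:
        if parameter in s.observed and parameter in s.predicted:
            a, ah = s.observed[parameter], s.predicted[parameter]
            if a <= 0 or ah <= 0:
                raise ValueError("non-positive summary value")
            logs.append(abs(np.log10(ah / a)))
    if not logs:
        raise ValueError(f"no studies report {parameter!r}")
    return float(10.0 ** np.mean(logs))


def rpred_obs(obs: float, pred: float) -> float:
    if obs <= 0:
        raise ValueError("observed value must be > 0")
    return pred / obs


def classify(ratio: float) -> str:
    """'within_1.25' | 'within_2' | 'outside'.

    |log10 R| is compared against the bounds at their printed precision
    (3 decimals), boundaries inclusive, so R = 2 and R = 0.5 classify as
    within_2 exactly.
    """
    al = round(abs(np.log10(ratio)), 3)
    if al <= LOG_1_25:
        return "within_1.25"
    if al <= LOG_2:
        return "within_2"
    return "outside"


def ddi_ratio_eval(control: StudySummary, coadmin: StudySummary,
                   obs_ratios: dict[str, float] | None = None
                   ) -> pd.DataFrame:
    """Predicted DDI ratios (per parameter) and, when observed ratios are
    given, their R_pred/obs and fold classification."""
    rows = []
    for k in control.predicted:
        if k not in coadmin.predicted or control.predicted[k] <= 0:
            continue
        pred_ratio = coadmin.predicted[k] / control.predicted[k]
        row = {"parameter": k, "pred_ratio": pred_ratio}
        if obs_ratios and k in obs_ratios:
            row["obs_ratio"] = obs_ratios[k]
            row["r_pred_obs"] = rpred_obs(obs_ratios[k], pred_ratio)
            row["class"] = classify(row["r_pred_obs"])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    mrd_by_study: pd.DataFrame
    gmfe_by_parameter: pd.DataFrame
    classification: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps({
            "mrd_by_study": self.mrd_by_study.to_dict("records"),
            "gmfe_by_parameter": self.gmfe_by_parameter.to_dict("records"),
            "classification": self.classification.to_dict("records")},
            indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(pd.DataFrame(d["mrd_by_study"]),
                   pd.DataFrame(d["gmfe_by_parameter"]),
                   pd.DataFrame(d["classification"]))


def report(pairs: list[ProfilePair],
           summaries: list[StudySummary]) -> EvaluationReport:
    """Assemble the evaluation tables: MRD per study, GMFE (with range) per
    parameter, and fold-criterion counts."""
    mrd_rows = [{"study": p.study, "mrd": mrd(p), "n": p.observed.size,
                 "n_excluded": p.n_excluded} for p in pairs]
    params = sorted({k for s in summaries for k in s.observed
                     if k in s.predicted})
    gm_rows, cl_rows = [], []
    for prm in params:
        ratios = [s.ratios()[prm] for s in summaries if prm in s.ratios()]
        gm_rows.append({"parameter": prm, "gmfe": gmfe(summaries, prm),
                        "min_ratio": min(ratios), "max_ratio": max(ratios),
                        "n_studies": len(ratios)})
        cls = [classify(r) for r in ratios]
        cl_rows.append({"parameter": prm,
                        "within_1.25": sum(c == "within_1.25" for c in cls),
                        "within_2": sum(c != "outside" for c in cls),
                        "total": len(cls)})
    return EvaluationReport(pd.DataFrame(mrd_rows), pd.DataFrame(gm_rows),
                            pd.DataFrame(cl_rows))
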