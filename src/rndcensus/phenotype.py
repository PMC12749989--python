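"""Phenotype arithmetic: plate-dilution scoring, MIC calling and
normalisation, and replicate time-course summaries.

Plate dilution assays (PDA) spot a 10-fold dilution series of culture on
drug plates; the score for a variant is the replicate-mean last dilution
step still showing growth, minus the wildtype mean for that drug (wildtype
scores are exactly 0).  MICs are called from background-corrected OD600
series: OD above the growth threshold (default 0.18) counts as growth, and
the MIC is the lowest concentration with no growth at it *and every higher
concentration* — the conservative reading for non-monotone (rebounding)
series.  Out-of-range MICs propagate through wildtype-normalised ratios as
censored inequalities (≥ / ≤), the microbiology convention, rather than as
numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ValidationError

logger = logging.getLogger("rndcensus")

GROWTH_THRESHOLD_DEFAULT = 0.18  # background-corrected OD600


@dataclass
class MICResult:
    """A called MIC with censoring: 'none', 'above' (> max) or 'below' (≤ min)."""

    value: float
    censored: str = "none"

    def __str__(self) -> str:
        if self.censored == "above":
            return f"> {self.value:g}"
        if self.censored == "below":
            return f"<= {self.value:g}"
        return f"{self.value:g}"


@dataclass
class ScoreEntry:
    """A wildtype-normalised phenotype score, possibly censored (ge/le)."""

    value: float
    censored: str = "none"   # 'none', 'ge', 'le', 'undefined'

    def __str__(self) -> str:
        if self.censored == "ge":
            return f">= {self.value:g}"
        if self.censored == "le":
            return f"<= {self.value:g}"
        if self.censored == "undefined":
            return "undefined"
        return f"{self.value:g}"


def pda_score(
    matrix: pd.DataFrame, wildtype_id: str
) -> pd.DataFrame:
    """Plate-dilution scores: replicate-mean last growth step minus wildtype.

    ``matrix`` columns: variant, drug, replicate, last_growth_step (integer
    dilution index, 10-fold steps, ≥ 0).  Returns a variant × drug frame of
    signed step differences; wildtype rows are exactly 0.
    """
    required = {"variant", "drug", "last_growth_step"}
    missing = required - set(matrix.columns)
    if missing:
        raise ValidationError(f"PDA matrix missing columns {sorted(missing)}")
    if (matrix["last_growth_step"] < 0).any():
        raise ValidationError("dilution indices must be ≥ 0")
    means = (
        matrix.groupby(["variant", "drug"])["last_growth_step"].mean().unstack()
    )
    if wildtype_id not in means.index:
        raise ValidationError(f"wildtype {wildtype_id!r} absent from matrix")
    wt = means.loc[wildtype_id]
    missing_drugs = wt[wt.isna()].index.tolist()
    if missing_drugs:
        raise ValidationError(
            f"wildtype {wildtype_id!r} missing for drugs: {missing_drugs}"
        )
    return means.sub(wt, axis=1)


def mic_call(
    concentrations,
    od_values,
    growth_threshold: float = GROWTH_THRESHOLD_DEFAULT,
) -> MICResult:
    """Call a MIC from a background-corrected OD series.

    MIC = lowest concentration c with OD ≤ threshold at c and at every
    higher concentration.  Growth at the top concentration → above-range
    (MIC > max); no growth anywhere → below-range (MIC ≤ min).
    """
    conc = np.asarray(concentrations, float)
    od = np.asarray(od_values, float)
    if conc.shape != od.shape or conc.ndim != 1 or len(conc) == 0:
        raise ValidationError("concentrations and OD values must be matching 1-D series")
    if not np.all(np.diff(conc) > 0):
        raise ValidationError("concentrations must be strictly increasing")
    if not np.all(np.isfinite(od)):
        raise ValidationError("OD values must be finite")
    growth = od > growth_threshold
    if growth[-1]:
        return MICResult(float(conc[-1]), "above")
    # last index with growth; MIC is the next concentration up
    grown = np.nonzero(growth)[0]
    if len(grown) == 0:
        return MICResult(float(conc[0]), "below")
    return MICResult(float(conc[grown[-1] + 1]))


def mic_normalize(
    mics: pd.DataFrame, wildtype_id: str
) -> pd.DataFrame:
    """Fold-change MIC scores: replicate-mean MIC ratio variant / wildtype.

    ``mics`` columns: variant, drug, replicate, mic (float), censored
    ('none'/'above'/'below').  Above-range MICs propagate as '≥' censored
    ratios; an above-range wildtype makes the ratio undefined.  Wildtype
    self-scores are exactly 1.
    """
    required = {"variant", "drug", "mic"}
    missing = required - set(mics.columns)
    if missing:
        raise ValidationError(f"MIC table missing columns {sorted(missing)}")
    df = mics.copy()
    if "censored" not in df.columns:
        df["censored"] = "none"
    if (df["mic"] <= 0).any():
        raise ValidationError("MIC values must be > 0")

    def agg(group: pd.DataFrame) -> tuple[float, str]:
        cens = set(group["censored"])
        mean = float(group["mic"].mean())
        if "above" in cens:
            return mean, "ge"
        if "below" in cens:
            return mean, "le"
        return mean, "none"

    summary: dict[tuple[str, str], tuple[float, str]] = {}
    for (variant, drug), group in df.groupby(["variant", "drug"]):
        summary[(variant, drug)] = agg(group)
    variants = sorted({v for v, _ in summary})
    drugs = sorted({d for _, d in summary})
    if wildtype_id not in variants:
        raise ValidationError(f"wildtype {wildtype_id!r} absent from MIC table")
    out = pd.DataFrame(index=variants, columns=drugs, dtype=object)
    for drug in drugs:
        wt = summary.get((wildtype_id, drug))
        if wt is None:
            raise ValidationError(
                f"wildtype {wildtype_id!r} has no MIC for drug {drug!r}"
            )
        wt_mean, wt_cens = wt
        for variant in variants:
            entry = summary.get((variant, drug))
            if entry is None:
                continue
            v_mean, v_cens = entry
            if wt_cens == "ge":
                # wildtype itself above range: no finite denominator
                out.loc[variant, drug] = ScoreEntry(np.nan, "undefined")
                continue
            ratio = v_mean / wt_mean
            if v_cens == "ge" or wt_cens == "le":
                out.loc[variant, drug] = ScoreEntry(ratio, "ge")
            elif v_cens == "le":
                out.loc[variant, drug] = ScoreEntry(ratio, "le")
            else:
                out.loc[variant, drug] = ScoreEntry(ratio)
    return out


def summarize_timecourse(
    curves: pd.DataFrame,
) -> pd.DataFrame:
    """Pointwise mean and sample SD (n−1) of replicate fluorescence curves.

    ``curves``: index = time, one column per replicate, all sharing the time
    grid (a frame with NaNs from mismatched grids is rejected).  Returns a
    frame with columns ``mean`` and ``sd``.
    """
    if curves.isna().any().any():
        raise ValidationError("replicates must share the time grid (NaNs found)")
    if curves.shape[1] == 0:
        raise ValidationError("no replicates")
    if curves.shape[1] == 1:
        logger.warning("single replicate: SD reported as 0")
        sd = pd.Series(0.0, index=curves.index)
    else:
        sd = curves.std(axis=1, ddof=1)
    return pd.DataFrame({"mean": curves.mean(axis=1), "sd": sd})
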