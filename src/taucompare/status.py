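"""Biomarker status calls: reference cut-offs, binarization, concordance and correlations.

Tau biomarkers are dichotomized against reference-population cut-offs
(mean + 2 SD in amyloid-negative cognitively normal individuals), pairs of
binary calls are cross-tabulated into 2x2 agreement quadrants, and continuous
markers are summarized with pairwise-complete Pearson correlation matrices.
Amyloid PET SUVR can be rescaled to the Centiloid scale per tracer.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POS = "POS"
NEG = "NEG"
MISSING = "MISSING"

#: Centiloid rescaling lines, per amyloid tracer: CL = slope * SUVR + intercept.
CENTILOID_LINES = {
    "florbetapir": (196.9, -196.03),
    "florbetaben": (159.08, -151.65),
}


@dataclass(frozen=True)
class Cutoff:
    """A dichotomization threshold for one biomarker.

    ``rule`` is ``"mean_plus_2sd"`` when derived from a reference population
    (then ``value == reference_mean + 2 * reference_sd``) or ``"external"``
    for previously published thresholds.
    """

    marker: str
    value: float
    rule: str = "external"
    reference_n: int | None = None
    reference_mean: float | None = None
    reference_sd: float | None = None

    def __post_init__(self) -> None:
        if self.rule == "mean_plus_2sd":
            expected = self.reference_mean + 2.0 * self.reference_sd
            if not math.isclose(self.value, expected, rel_tol=0, abs_tol=1e-12 * max(1.0, abs(expected))):
                raise ValueError(
                    f"mean_plus_2sd cutoff for {self.marker!r} must equal "
                    f"reference_mean + 2*reference_sd (got {self.value}, expected {expected})"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class QuadrantTable:
    """2x2 positive/negative agreement counts for a pair of binarized markers.

    Cell naming follows marker A x marker B: ``n_pos_neg`` counts rows where A
    is positive and B negative. ``n_excluded`` counts pairs dropped because
    either call was missing.
    """

    marker_a: str
    marker_b: str
    n_pos_pos: int
    n_pos_neg: int
    n_neg_pos: int
    n_neg_neg: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for cell in (self.n_pos_pos, self.n_pos_neg, self.n_neg_pos, self.n_neg_neg):
            if cell < 0:
                raise ValueError("quadrant counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_pos_pos + self.n_pos_neg + self.n_neg_pos + self.n_neg_neg

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations over a named variable list."""

    variables: list[str]
    r: np.ndarray
    n: np.ndarray
    #: boolean mask of cells flagged undefined (constant variable on the complete pairs)
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros_like(self.r, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


def derive_cutoff(reference_values: Iterable[float], marker: str = "marker") -> Cutoff:
    """Derive a mean + 2*SD cut-off from a reference population.

    The reference population is, by construction downstream, the
    amyloid-negative cognitively unimpaired subgroup. Sample SD uses the
    n-1 denominator.

    Raises ``ValueError`` on fewer than two values or any non-finite value.
    """
    values = np.asarray(list(reference_values), dtype=float)
    if values.size < 2:
        raise ValueError("cutoff derivation needs at least 2 reference values")
    if not np.all(np.isfinite(values)):
        raise ValueError("cutoff derivation requires finite reference values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return Cutoff(
        marker=marker,
        value=mean + 2.0 * sd,
        rule="mean_plus_2sd",
        reference_n=int(values.size),
        reference_mean=mean,
        reference_sd=sd,
    )


def binarize(values: Iterable[float], cutoff: Cutoff) -> list[str]:
    """Call POS/NEG against a cut-off; strictly greater than the cut-off is POS.

    Missing (NaN/None) input propagates as ``MISSING``.
    """
    if not math.isfinite(cutoff.value):
        raise ValueError("cutoff value must be finite")
    calls = []
    n_missing = 0
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            calls.append(MISSING)
            n_missing += 1
        else:
            calls.append(POS if float(v) > cutoff.value else NEG)
    if calls and n_missing == len(calls):
        logger.warning("binarize(%s): all %d values missing", cutoff.marker, len(calls))
    return calls


def quadrant_table(
    calls_a: Sequence[str],
    calls_b: Sequence[str],
    marker_a: str = "A",
    marker_b: str = "B",
) -> QuadrantTable:
    """Cross-tabulate two call vectors into a 2x2 quadrant table.

    Pairs with a MISSING call on either side are excluded and counted in
    ``n_excluded``. Raises if no complete pair remains.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("call vectors must have equal length")
    counts = {("POS", "POS"): 0, ("POS", "NEG"): 0, ("NEG", "POS"): 0, ("NEG", "NEG"): 0}
    excluded = 0
    for a, b in zip(calls_a, calls_b):
        if a == MISSING or b == MISSING:
            excluded += 1
        else:
            counts[(a, b)] += 1
    table = QuadrantTable(
        marker_a=marker_a,
        marker_b=marker_b,
        n_pos_pos=counts[("POS", "POS")],
        n_pos_neg=counts[("POS", "NEG")],
        n_neg_pos=counts[("NEG", "POS")],
        n_neg_neg=counts[("NEG", "NEG")],
        n_excluded=excluded,
    )
    if table.total == 0:
        raise ValueError("no complete pairs to tabulate")
    return table


def concordance_percent(q: QuadrantTable) -> dict[str, float]:
    """Percent agreement of a quadrant table, with both discordance rates.

    Returns ``concordance`` = 100*(++ + --)/total along with
    ``discordant_a_pos`` (A+/B-) and ``discordant_b_pos`` (A-/B+); the three
    sum to 100 up to floating point.
    """
    if q.total == 0:
        raise ValueError("empty quadrant table")
    total = q.total
    return {
        "concordance": 100.0 * (q.n_pos_pos + q.n_neg_neg) / total,
        "discordant_a_pos": 100.0 * q.n_pos_neg / total,
        "discordant_b_pos": 100.0 * q.n_neg_pos / total,
        "n": total,
        "n_excluded": q.n_excluded,
    }


def correlation_matrix(table: pd.DataFrame, variables: Sequence[str]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix over ``variables``.

    Each off-diagonal entry uses all rows where both variables are observed
    (requiring at least 3 complete pairs). A pair where either variable is
    constant over the complete rows has an undefined correlation; the cell is
    set to NaN and flagged rather than silently propagated.
    """
    variables = list(variables)
    missing_cols = [v for v in variables if v not in table.columns]
    if missing_cols:
        raise KeyError(f"variables not in table: {missing_cols}")
    p = len(variables)
    r = np.eye(p)
    n = np.zeros((p, p), dtype=int)
    flagged = np.zeros((p, p), dtype=bool)
    cols = {v: pd.to_numeric(table[v], errors="coerce").to_numpy(dtype=float) for v in variables}
    for i in range(p):
        n[i, i] = int(np.isfinite(cols[variables[i]]).sum())
    for i in range(p):
        xi = cols[variables[i]]
        for j in range(i + 1, p):
            xj = cols[variables[j]]
            ok = np.isfinite(xi) & np.isfinite(xj)
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({variables[i]}, {variables[j]})"
                )
            a, b = xi[ok], xj[ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                r[i, j] = r[j, i] = np.nan
                flagged[i, j] = flagged[j, i] = True
                logger.warning(
                    "correlation undefined for constant variable in pair (%s, %s)",
                    variables[i], variables[j],
                )
            else:
                r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
    return CorrelationMatrix(variables=variables, r=r, n=n, flagged=flagged)


def to_centiloid(suvr: float | np.ndarray, tracer: str) -> float | np.ndarray:
    """Rescale amyloid PET SUVR to the Centiloid scale for a known tracer."""
    if tracer not in CENTILOID_LINES:
        raise ValueError(f"unknown tracer {tracer!r}; expected one of {sorted(CENTILOID_LINES)}")
    arr = np.asarray(suvr, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("SUVR must be positive")
    slope, intercept = CENTILOID_LINES[tracer]
    out = slope * arr + intercept
    return float(out) if np.isscalar(suvr) else out
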