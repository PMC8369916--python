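"""Aggregation of per-cell measurements into variant profiles.

Functional characterization of an ion-channel variant produces many small
per-cell samples (fitted EC50s, time constants, potentiation ratios, assay
ratios).  This module provides the summary statistics used throughout the
package — mean with a Student-t 95% confidence interval, the classic
pooled-variance unpaired t-test, percent response ratios — and the
``VariantProfile`` container that collects one construct's full
characterization into a serializable record.

Ratio-valued quantities (percent-of-WT, fold potentiation) are summarized on
the log scale and exponentiated, since such quantities are right-skewed by
construction; :func:`mean_ci95_log` implements this and records the choice.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStats",
    "VariantProfile",
    "mean_ci95",
    "mean_ci95_log",
    "unpaired_t",
    "response_ratio",
    "assemble_profile",
]


@dataclass(frozen=True)
class GroupStats:
    """Mean with 95% confidence interval over ``n`` independent cells/experiments."""

    mean: float
    ci95_low: float
    ci95_high: float
    n: int
    unit: str = ""
    degenerate: bool = False  # n < 2: CI not estimable
    scale: str = "linear"  # "linear" or "log" (geometric summary)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("GroupStats requires n >= 1")
        if not self.degenerate and not (
            self.ci95_low <= self.mean <= self.ci95_high
        ):
            raise ValueError("CI must bracket the mean")


def mean_ci95(values: Sequence[float], unit: str = "") -> GroupStats:
    """Arithmetic mean with a t-distribution 95% CI (df = n - 1).

    A single value yields a degenerate, flagged interval rather than an error:
    sparse assays are common and a point estimate is still reportable.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_ci95 requires at least one value")
    m = float(arr.mean())
    if arr.size < 2:
        return GroupStats(m, m, m, 1, unit=unit, degenerate=True)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    tcrit = float(stats.t.ppf(0.975, arr.size - 1))
    return GroupStats(m, m - tcrit * sem, m + tcrit * sem, int(arr.size), unit=unit)


def mean_ci95_log(values: Sequence[float], unit: str = "") -> GroupStats:
    """Geometric mean with 95% CI computed on the log scale.

    Used for strictly positive ratio quantities (percent-of-WT, potentiation),
    which are multiplicative and right-skewed.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_ci95_log requires at least one value")
    if np.any(arr <= 0):
        raise ValueError("log-scale summary requires strictly positive values")
    logs = np.log(arr)
    g = mean_ci95(logs.tolist())
    return GroupStats(
        math.exp(g.mean),
        math.exp(g.ci95_low),
        math.exp(g.ci95_high),
        g.n,
        unit=unit,
        degenerate=g.degenerate,
        scale="log",
    )


def unpaired_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided unpaired Student's t-test (pooled variance by default).

    Returns ``(t, p)``.  ``welch=True`` switches to the unequal-variance form.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired_t requires n >= 2 in each group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def response_ratio(numerator_amp: float, denominator_amp: float) -> float:
    """Percent ratio of two response amplitudes (100 x num / den).

    Serves pH sensitivity (I at pH 6.8 vs 7.6), positive-modulator
    potentiation (I with PAM vs control), and percent inhibition
    (as 100 minus the returned value).
    """
    if denominator_amp == 0:
        raise ValueError("denominator amplitude must be nonzero")
    return 100.0 * numerator_amp / denominator_amp


@dataclass
class VariantProfile:
    """Machine-readable characterization record for one construct.

    ``fields`` maps parameter names (e.g. ``glutamate_ec50_uM``) to
    :class:`GroupStats`; assays not performed are explicitly ``None``, never
    zero.  ``provenance`` records, per field, which assay/fit produced it.
    """

    construct: str
    fields: dict[str, GroupStats | None] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    n_tests_performed: int = 0  # t-tests run while assembling; no correction applied

    def to_json(self) -> str:
        def enc(v):
            if v is None:
                return None
            return dataclasses.asdict(v)

        return json.dumps(
            {
                "construct": self.construct,
                "fields": {k: enc(v) for k, v in self.fields.items()},
                "provenance": self.provenance,
                "n_tests_performed": self.n_tests_performed,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "VariantProfile":
        raw = json.loads(text)
        fields = {
            k: (GroupStats(**v) if v is not None else None)
            for k, v in raw["fields"].items()
        }
        return cls(
            construct=raw["construct"],
            fields=fields,
            provenance=dict(raw.get("provenance", {})),
            n_tests_performed=int(raw.get("n_tests_performed", 0)),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, gs in sorted(self.fields.items()):
            if gs is None:
                rows.append(
                    {"construct": self.construct, "parameter": name, "mean": None,
                     "ci95_low": None, "ci95_high": None, "n": None, "unit": None}
                )
            else:
                rows.append(
                    {"construct": self.construct, "parameter": name, "mean": gs.mean,
                     "ci95_low": gs.ci95_low, "ci95_high": gs.ci95_high,
                     "n": gs.n, "unit": gs.unit}
                )
        return pd.DataFrame(rows)


def assemble_profile(
    construct: str,
    measurements: Mapping[str, tuple[Iterable[float], str] | GroupStats | None],
    provenance: Mapping[str, str] | None = None,
    log_scale_fields: Iterable[str] = (),
) -> VariantProfile:
    """Build a :class:`VariantProfile` from per-assay raw values.

    ``measurements`` maps field name to either ``(values, unit)`` — summarized
    here — or an already-computed :class:`GroupStats`, or ``None`` for an assay
    that was not performed.  Fields named in ``log_scale_fields`` are
    summarized geometrically.
    """
    if not measurements or all(v is None for v in measurements.values()):
        raise ValueError("assemble_profile requires at least one populated assay")
    log_fields = set(log_scale_fields)
    out: dict[str, GroupStats | None] = {}
    for name, spec in measurements.items():
        if spec is None:
            out[name] = None
        elif isinstance(spec, GroupStats):
            out[name] = spec
        else:
            values, unit = spec
            summarize = mean_ci95_log if name in log_fields else mean_ci95
            out[name] = summarize(list(values), unit=unit)
    return VariantProfile(
        construct=construct,
        fields=out,
        provenance=dict(provenance or {}),
    )
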