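"""Cumulative (absolute) risk for variant carriers from age-specific odds
ratios and population incidence.

The standard constrained-incidence scheme: given a population incidence
curve lambda_pop(t) on 5-year bands, a carrier frequency f at birth, and
an age-specific relative risk RR(t) (approximated by the odds ratio
under the rare-disease assumption), the non-carrier baseline hazard in
each band is constrained so the survivor-weighted mixture of carrier and
non-carrier hazards reproduces the population incidence:

    lambda_0(t) = lambda_pop(t) * [f S1(t) + (1-f) S0(t)]
                  / [f S1(t) RR(t) + (1-f) S0(t)]
    lambda_1(t) = RR(t) * lambda_0(t)

with disease-free survivor fractions S1, S0 (both 1 at age 0) updated
band-by-band as S <- S * exp(-lambda * dt).  Cumulative risk "in the
absence of other events" (no competing mortality) is F(T) = 1 - S(T).
Confidence bands are produced by re-running the whole recursion at the
OR's CI bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceTable",
    "RiskCurve",
    "constrained_baseline",
    "cumulative_risk_curve",
    "threshold_report",
    "population_cumulative_risk",
]


class RareDiseaseWarning(UserWarning):
    """The RR ~ OR approximation is strained (large per-band risk)."""


@dataclass
class IncidenceTable:
    """Piecewise-constant population incidence on contiguous age bands
    starting at 0 (rates per person-year)."""

    bands: pd.DataFrame  # age_start, age_end, rate_per_py

    def __post_init__(self):
        b = self.bands
        required = {"age_start", "age_end", "rate_per_py"}
        if missing := required - set(b.columns):
            raise ValueError(f"incidence table missing columns: {sorted(missing)}")
        if len(b) == 0:
            raise ValueError("incidence table is empty")
        if b["age_start"].iloc[0] != 0:
            raise ValueError("incidence bands must start at age 0")
        if not np.all(b["age_end"].to_numpy()[:-1] == b["age_start"].to_numpy()[1:]):
            raise ValueError("incidence bands must be contiguous")
        if np.any(b["rate_per_py"].to_numpy() < 0):
            raise ValueError("incidence rates must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "IncidenceTable":
        return cls(pd.read_csv(path))

    @property
    def age_max(self) -> float:
        return float(self.bands["age_end"].iloc[-1])

    def rates(self) -> np.ndarray:
        return self.bands["rate_per_py"].to_numpy(dtype=float)

    def widths(self) -> np.ndarray:
        return (self.bands["age_end"] - self.bands["age_start"]).to_numpy(dtype=float)

    def midpoints(self) -> np.ndarray:
        return (
            (self.bands["age_start"] + self.bands["age_end"]) / 2.0
        ).to_numpy(dtype=float)


def population_cumulative_risk(inc: IncidenceTable, age: float | None = None) -> float:
    """1 - exp(-integral of the population hazard) up to ``age``."""
    if age is None:
        age = inc.age_max
    lam = inc.rates()
    starts = inc.bands["age_start"].to_numpy(dtype=float)
    ends = np.minimum(inc.bands["age_end"].to_numpy(dtype=float), age)
    dt = np.clip(ends - starts, 0.0, None)
    return float(1.0 - np.exp(-np.sum(lam * dt)))


def constrained_baseline(
    or_fn: Callable[[float], float],
    inc: IncidenceTable,
    f: float,
) -> pd.DataFrame:
    """Per-band carrier/non-carrier hazards under the mixture constraint.

    ``or_fn`` maps age (band midpoint) to the odds ratio, taken as the
    relative risk under the rare-disease approximation; ``f`` is the
    carrier frequency at birth.  Returns a frame with lam0, lam1 and the
    survivor fractions S0, S1 at each band start.
    """
    if not (0.0 <= f < 1.0):
        raise ValueError(f"carrier frequency f={f} must be in [0, 1)")
    lam_pop = inc.rates()
    mids = inc.midpoints()
    dt = inc.widths()
    rr = np.array([float(or_fn(t)) for t in mids])
    if np.any(rr <= 0):
        raise ValueError("odds ratios must be positive")
    if np.any(lam_pop * rr * dt > 0.1):
        warnings.warn(
            "band incidence x RR x width exceeds 0.1; the rare-disease "
            "RR ~ OR approximation may be inaccurate",
            RareDiseaseWarning,
            stacklevel=2,
        )
    s0, s1 = 1.0, 1.0
    rows = []
    for i in range(len(lam_pop)):
        mix = f * s1 + (1.0 - f) * s0
        denom = f * s1 * rr[i] + (1.0 - f) * s0
        lam0 = lam_pop[i] * mix / denom if denom > 0 else 0.0
        lam1 = rr[i] * lam0
        rows.append(
            {
                "age_start": float(inc.bands["age_start"].iloc[i]),
                "age_end": float(inc.bands["age_end"].iloc[i]),
                "rate_pop": float(lam_pop[i]),
                "rr": float(rr[i]),
                "lam0": float(lam0),
                "lam1": float(lam1),
                "S0_start": s0,
                "S1_start": s1,
            }
        )
        s0 *= float(np.exp(-lam0 * dt[i]))
        s1 *= float(np.exp(-lam1 * dt[i]))
    return pd.DataFrame(rows)


@dataclass
class RiskCurve:
    """Carrier cumulative risk F1 and baseline F0 on an age grid, with a
    CI band propagated from the OR's confidence bounds."""

    ages: np.ndarray  # grid including 0
    f1: np.ndarray
    f0: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    carrier_freq: float
    label: str = ""

    def __post_init__(self):
        for name in ("f1", "f0", "ci_low", "ci_high"):
            v = getattr(self, name)
            if np.any(np.diff(v) < -1e-12):
                raise ValueError(f"{name} must be non-decreasing")
        if not (self.f1[0] == 0 and self.f0[0] == 0):
            raise ValueError("cumulative risk must start at 0")

    def at(self, age: float, which: str = "f1") -> float:
        return float(np.interp(age, self.ages, getattr(self, which)))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "carrier_risk": self.f1,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "baseline_risk": self.f0,
            }
        )


def _risk_from_or_fn(
    or_fn: Callable[[float], float], inc: IncidenceTable, f: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    haz = constrained_baseline(or_fn, inc, f)
    dt = inc.widths()
    cum1 = np.concatenate([[0.0], np.cumsum(haz["lam1"].to_numpy() * dt)])
    cum0 = np.concatenate([[0.0], np.cumsum(haz["lam0"].to_numpy() * dt)])
    ages = np.concatenate(
        [[float(inc.bands["age_start"].iloc[0])], inc.bands["age_end"].to_numpy(dtype=float)]
    )
    return ages, 1.0 - np.exp(-cum1), 1.0 - np.exp(-cum0)


def cumulative_risk_curve(
    or_hat: float,
    inc: IncidenceTable,
    f: float,
    ci: tuple[float, float] | None = None,
    or_age_multiplier: float | None = None,
    age_ref: float = 50.0,
    label: str = "",
) -> RiskCurve:
    """Carrier cumulative-risk curve from an estimated OR (optionally with
    a log-linear per-year age multiplier) and a population incidence.

    When ``or_age_multiplier`` m is given, the age-specific odds ratio is
    OR(t) = or_hat * m**(t - age_ref); the CI band re-runs the recursion
    at the OR CI bounds (multiplier held at its point estimate).
    """

    def make_fn(o: float) -> Callable[[float], float]:
        if or_age_multiplier is None:
            return lambda t: o
        return lambda t: o * or_age_multiplier ** (t - age_ref)

    ages, f1, f0 = _risk_from_or_fn(make_fn(or_hat), inc, f)
    if ci is not None:
        lo, hi = ci
        _, f1_lo, _ = _risk_from_or_fn(make_fn(lo), inc, f)
        _, f1_hi, _ = _risk_from_or_fn(make_fn(hi), inc, f)
    else:
        f1_lo, f1_hi = f1.copy(), f1.copy()
    return RiskCurve(
        ages=ages, f1=f1, f0=f0, ci_low=f1_lo, ci_high=f1_hi,
        carrier_freq=f, label=label,
    )


def threshold_report(
    curves: Mapping[str, RiskCurve],
    threshold: float = 0.30,
    age: float = 80.0,
) -> pd.DataFrame:
    """Classify each curve as high-risk or not at the threshold age
    (default: 30% cumulative risk by 80, the NICE surveillance
    criterion)."""
    rows = []
    for name, curve in curves.items():
        if curve.ages[-1] < age:
            raise ValueError(
                f"curve {name!r} ends at age {curve.ages[-1]}, before threshold age {age}"
            )
        risk = curve.at(age)
        rows.append(
            {
                "unit": name,
                "age": age,
                "cumulative_risk": risk,
                "ci_low": curve.at(age, "ci_low"),
                "ci_high": curve.at(age, "ci_high"),
                "threshold": threshold,
                "high_risk": bool(risk >= threshold),
            }
        )
    return pd.DataFrame(rows)


def plot_risk_curves(curves: Mapping[str, RiskCurve], path=None):
    """Optional matplotlib plot of carrier risk curves with CI bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, c in curves.items():
        (line,) = ax.plot(c.ages, 100 * c.f1, label=name)
        ax.fill_between(c.ages, 100 * c.ci_low, 100 * c.ci_high,
                        alpha=0.15, color=line.get_color())
    if curves:
        first = next(iter(curves.values()))
        ax.plot(first.ages, 100 * first.f0, "k--", label="population baseline")
    ax.axhline(30, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Cumulative risk (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
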