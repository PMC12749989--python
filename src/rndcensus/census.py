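"""Trimer-composition census: reconstruct the distribution of trimeric
conformational states from per-monomer labels, with uncertainty and a test
of monomer-independence.

A trimer composition is the unordered multiset of its three protomer
states; its canonical name sorts the labels by the fixed precedence
L < T < O < O* and concatenates them, so the aliases "OTT" and "TTO" both
canonicalise to "TTO".  Monomer frequencies and trimer frequencies are tied
by the exact identity f_s = Σ_c p(c) · n_s(c) / 3, which the census
enforces structurally (both are computed from the same complete particles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    STATE_PRECEDENCE,
    STATES,
    UNASSIGNED,
    LabelTable,
    ValidationError,
)


class EmptyCensusError(ValueError):
    """No complete particles to aggregate."""


def parse_composition(name: str) -> tuple[str, ...]:
    """Split a composition name into state labels ("OO*O*" → (O, O*, O*))."""
    labels: list[str] = []
    i = 0
    while i < len(name):
        if i + 1 < len(name) and name[i + 1] == "*":
            labels.append(name[i : i + 2])
            i += 2
        else:
            labels.append(name[i])
            i += 1
    bad = [l for l in labels if l not in STATES]
    if bad:
        raise ValidationError(f"unknown state labels {bad} in composition {name!r}")
    return tuple(labels)


def canonical_composition(labels: tuple[str, ...] | list[str]) -> str:
    """Canonical name of a 3-state multiset: sorted by precedence L<T<O<O*."""
    if len(labels) != 3:
        raise ValidationError(f"a trimer composition has 3 labels, got {len(labels)}")
    bad = [l for l in labels if l not in STATES]
    if bad:
        raise ValidationError(f"unknown state labels {bad}")
    return "".join(sorted(labels, key=STATE_PRECEDENCE.__getitem__))


def canonicalize_name(name: str) -> str:
    """Canonicalise an alias composition name ("OTT" → "TTO")."""
    return canonical_composition(list(parse_composition(name)))


def state_counts(composition: str) -> dict[str, int]:
    """n_s(c): per-state multiplicities of a composition."""
    counts = {s: 0 for s in STATES}
    for l in parse_composition(composition):
        counts[l] += 1
    return counts


@dataclass
class TrimerComposition:
    """Unordered multiset of three protomer state labels."""

    labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        self.labels = tuple(
            sorted(self.labels, key=STATE_PRECEDENCE.__getitem__)
        )  # type: ignore[assignment]

    @property
    def canonical_name(self) -> str:
        return "".join(self.labels)

    def __hash__(self) -> int:
        return hash(self.labels)


@dataclass
class StateCensus:
    """Monomer- and trimer-level counts and frequencies over complete particles."""

    n_particles_complete: int
    n_particles_dropped: int
    monomer_counts: dict[str, int]
    monomer_freqs: dict[str, float]
    trimer_counts: dict[str, int]
    trimer_freqs: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_particles_complete > 0:
            if abs(sum(self.monomer_freqs.values()) - 1.0) > 1e-12:
                raise ValidationError("monomer frequencies must sum to 1")
            if abs(sum(self.trimer_freqs.values()) - 1.0) > 1e-12:
                raise ValidationError("trimer frequencies must sum to 1")
            if sum(self.monomer_counts.values()) != 3 * self.n_particles_complete:
                raise ValidationError(
                    "monomer counts must total 3 × complete particles"
                )

    def to_dict(self) -> dict:
        return {
            "n_particles_complete": self.n_particles_complete,
            "n_particles_dropped": self.n_particles_dropped,
            "monomer_counts": self.monomer_counts,
            "monomer_freqs": self.monomer_freqs,
            "trimer_counts": self.trimer_counts,
            "trimer_freqs": self.trimer_freqs,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }

    def summary_frame(self) -> pd.DataFrame:
        """Two-panel summary: per-state and per-composition percentages."""
        rows = []
        for s in STATES:
            if self.monomer_counts.get(s, 0) or self.monomer_freqs.get(s, 0):
                rows.append(
                    ("monomer", s, self.monomer_counts.get(s, 0),
                     round(100 * self.monomer_freqs.get(s, 0.0), 1))
                )
        for c in sorted(self.trimer_counts):
            rows.append(
                ("trimer", c, self.trimer_counts[c],
                 round(100 * self.trimer_freqs[c], 1))
            )
        return pd.DataFrame(rows, columns=["level", "state", "count", "percent"])


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _complete_compositions(labels: LabelTable) -> tuple[list[str], int]:
    """Canonical composition per complete particle + number of dropped particles.

    A particle is complete when all three copies are present and assigned
    (no UNASSIGNED); anything else is dropped and reported.
    """
    df = labels.df
    comps: list[str] = []
    dropped = 0
    for _, group in df.groupby("particle_id", sort=True):
        states = group["state_label"].tolist()
        if len(states) == 3 and all(s != UNASSIGNED for s in states):
            comps.append(canonical_composition(states))
        else:
            dropped += 1
    return comps, dropped


def _census_from_compositions(
    comps: list[str], dropped: int
) -> StateCensus:
    n = len(comps)
    if n == 0:
        raise EmptyCensusError("zero complete particles")
    trimer_counts: dict[str, int] = {}
    for c in comps:
        trimer_counts[c] = trimer_counts.get(c, 0) + 1
    monomer_counts = {s: 0 for s in STATES}
    for c, k in trimer_counts.items():
        for s, m in state_counts(c).items():
            monomer_counts[s] += m * k
    total_mono = 3 * n
    return StateCensus(
        n_particles_complete=n,
        n_particles_dropped=dropped,
        monomer_counts=monomer_counts,
        monomer_freqs={s: monomer_counts[s] / total_mono for s in STATES},
        trimer_counts=dict(sorted(trimer_counts.items())),
        trimer_freqs={c: k / n for c, k in sorted(trimer_counts.items())},
    )


def aggregate_census(labels: LabelTable) -> StateCensus:
    """Aggregate per-monomer labels into a monomer/trimer state census.

    Particles with exactly three assigned monomers form compositions;
    incomplete or partially unassigned particles are dropped and counted in
    ``n_particles_dropped``.  Frequencies are over complete particles only.
    """
    if len(labels) == 0:
        raise ValidationError("empty label table")
    comps, dropped = _complete_compositions(labels)
    return _census_from_compositions(comps, dropped)


def implied_monomer_frequencies(
    trimer_freqs: Mapping[str, float]
) -> dict[str, float]:
    """Monomer frequencies implied by a composition distribution.

    f_s = Σ_c p(c) · n_s(c) / 3.  Alias names are accepted and
    canonicalised.  The input must sum to 1 within 1e-6; renormalisation is
    refused (callers must do that deliberately).
    """
    if any(v < 0 for v in trimer_freqs.values()):
        raise ValidationError("composition frequencies must be non-negative")
    total = sum(trimer_freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(
            f"composition frequencies sum to {total:.8f}, not 1; "
            "renormalize explicitly if intended"
        )
    f = {s: 0.0 for s in STATES}
    for name, p in trimer_freqs.items():
        for s, m in state_counts(canonicalize_name(name)).items():
            f[s] += p * m / 3.0
    return f


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_census(
    labels: LabelTable, B: int = 200, seed: int = 0
) -> StateCensus:
    """Particle-level nonparametric bootstrap; percentile 95% CIs.

    Particles are resampled whole (their three labels stay together),
    preserving intra-trimer correlation.  Interval keys are
    ``monomer:<state>`` and ``trimer:<composition>``.
    """
    if B < 1:
        raise ValidationError("B must be ≥ 1")
    comps, dropped = _complete_compositions(labels)
    census = _census_from_compositions(comps, dropped)
    names = sorted(set(comps))
    name_idx = {c: i for i, c in enumerate(names)}
    codes = np.array([name_idx[c] for c in comps])
    n = len(codes)
    # per-composition state multiplicity matrix (len(names) × len(STATES))
    M = np.array([[state_counts(c)[s] for s in STATES] for c in names], float)
    rng = np.random.default_rng(seed)
    samples = rng.integers(0, n, size=(B, n))
    trimer_reps = np.empty((B, len(names)))
    for b in range(B):
        counts = np.bincount(codes[samples[b]], minlength=len(names))
        trimer_reps[b] = counts / n
    mono_reps = trimer_reps @ M / 3.0
    ci: dict[str, tuple[float, float]] = {}
    for j, s in enumerate(STATES):
        lo, hi = np.percentile(mono_reps[:, j], [2.5, 97.5])
        ci[f"monomer:{s}"] = (float(lo), float(hi))
    for j, c in enumerate(names):
        lo, hi = np.percentile(trimer_reps[:, j], [2.5, 97.5])
        ci[f"trimer:{c}"] = (float(lo), float(hi))
    census.ci = ci
    return census


# ---------------------------------------------------------------------------
# Independence test
# ---------------------------------------------------------------------------

def _all_compositions(states: list[str]) -> list[str]:
    """All multisets of size 3 over the given states, canonical names."""
    out = set()
    for a in states:
        for b in states:
            for c in states:
                out.add(canonical_composition((a, b, c)))
    return sorted(out)


def multinomial_composition_probability(
    composition: str, monomer_freqs: Mapping[str, float]
) -> float:
    """P(c) under independent monomer states:
    (3! / Π_s n_s(c)!) · Π_s f_s^{n_s(c)}."""
    from math import factorial

    ns = state_counts(composition)
    coeff = factorial(3)
    p = 1.0
    for s, m in ns.items():
        coeff //= factorial(m)
        p *= monomer_freqs.get(s, 0.0) ** m
    return coeff * p


def independence_test(census: StateCensus) -> tuple[float, int, float]:
    """G-test of trimer compositions against the independent-monomer null.

    Expected composition probabilities use the observed monomer frequencies;
    categories with expected count < 1 are pooled into one.  Degrees of
    freedom: (#categories after pooling) − (#states with nonzero frequency).
    Returns (G, dof, p).
    """
    n = census.n_particles_complete
    if n < 1:
        raise EmptyCensusError("no complete particles")
    active_states = [s for s in STATES if census.monomer_freqs.get(s, 0) > 0]
    comps = _all_compositions(active_states)
    if len(active_states) == 1:
        return 0.0, 0, 1.0
    expected = np.array(
        [
            n * multinomial_composition_probability(c, census.monomer_freqs)
            for c in comps
        ]
    )
    observed = np.array([census.trimer_counts.get(c, 0) for c in comps], float)
    # pool sparse categories (expected < 1) into one
    pool = expected < 1.0
    if pool.any():
        obs = np.concatenate([observed[~pool], [observed[pool].sum()]])
        exp = np.concatenate([expected[~pool], [expected[pool].sum()]])
    else:
        obs, exp = observed, expected
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    nz = obs > 0
    g = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    dof = len(exp) - len(active_states)
    if dof <= 0:
        return max(g, 0.0), max(dof, 0), 1.0
    p = float(stats.chi2.sf(g, dof))
    return g, dof, p
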