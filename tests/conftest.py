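"""Shared fixtures: machines, hand-built arcs, and random small-arc factories."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from arcqa.plan_model import ArcBeam, ControlPoint, MachineSpec


@pytest.fixture(scope="session")
def machine() -> MachineSpec:
    return MachineSpec()


def build_arc(bank_a_list, bank_b_list, machine, cum_weights=None,
              gantry=None, total_mu=200.0, dose_per_fraction=20.0,
              jaws=(-110.0, 110.0, -110.0, 110.0), arc_id="toy") -> ArcBeam:
    """Assemble an ArcBeam from per-CP bank arrays."""
    n = len(bank_a_list)
    if cum_weights is None:
        cum_weights = np.linspace(0.0, 1.0, n)
    if gantry is None:
        gantry = np.linspace(180.0, 180.0 - 2.0 * (n - 1), n) % 360.0
    cps = [ControlPoint(index=i, cum_weight=float(cum_weights[i]),
                        gantry_angle=float(gantry[i]),
                        bank_a=np.asarray(bank_a_list[i], float),
                        bank_b=np.asarray(bank_b_list[i], float), jaws=jaws)
           for i in range(n)]
    return ArcBeam(arc_id=arc_id, patient_id="pt", treatment_date=dt.date(2022, 6, 1),
                   control_points=cps, total_mu=total_mu,
                   dose_per_fraction=dose_per_fraction, machine=machine)


def uniform_banks(pairs_and_intervals, park=0.0):
    """One CP's banks: dict {pair_index: (a, b)}; other pairs closed at park."""
    a = np.full(60, park)
    b = np.full(60, park)
    for i, (lo, hi) in pairs_and_intervals.items():
        a[i], b[i] = lo, hi
    return a, b


def random_small_arc(rng, machine, n_cp=None, max_open_pairs=8,
                     snap=0.1) -> ArcBeam:
    """A small random arc with positions snapped to the 0.1 mm grid.

    Snapping makes the rasterization oracles exact.  Gaps are either zero
    (closed) or comfortably above min_gap.
    """
    n_cp = n_cp or int(rng.integers(3, 11))
    n_open = int(rng.integers(1, max_open_pairs + 1))
    first = int(rng.integers(20, 40 - n_open))
    open_idx = np.arange(first, first + n_open)

    bank_a = np.zeros((n_cp, 60))
    bank_b = np.zeros((n_cp, 60))
    centers = rng.uniform(-20, 20, (n_cp, n_open))
    gaps = rng.uniform(2.0, 30.0, (n_cp, n_open))
    bank_a[:, open_idx] = np.round((centers - gaps / 2) / snap) * snap
    bank_b[:, open_idx] = np.round((centers + gaps / 2) / snap) * snap
    # occasionally close a random open pair at one CP
    if n_cp >= 3 and rng.random() < 0.5:
        k = int(rng.integers(n_cp))
        i = open_idx[int(rng.integers(n_open))]
        bank_a[k, i] = bank_b[k, i] = 0.0

    inc = rng.uniform(0.3, 1.0, n_cp - 1)
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    cum /= cum[-1]
    start = float(rng.uniform(0, 360))
    gantry = (start - np.linspace(0, rng.uniform(10, 90), n_cp)) % 360
    cps = [ControlPoint(index=i, cum_weight=float(cum[i]),
                        gantry_angle=float(gantry[i]),
                        bank_a=bank_a[i], bank_b=bank_b[i])
           for i in range(n_cp)]
    return ArcBeam(arc_id=f"rnd{rng.integers(1 << 30)}", patient_id="pt",
                   treatment_date=dt.date(2022, 1, 1), control_points=cps,
                   total_mu=float(rng.uniform(50, 400)),
                   dose_per_fraction=float(rng.uniform(5, 25)), machine=machine)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_small_arcs(machine):
    """100 random small arcs shared by the metric-oracle tests."""
    rng = np.random.default_rng(7)
    return [random_small_arc(rng, machine) for _ in range(100)]


@pytest.fixture(scope="session")
def cohort_features():
    """Extracted 18-feature table of a reduced synthetic cohort (~600 arcs)."""
    from arcqa.cohort import CohortConfig, generate_cohort
    from arcqa.complexity import extract_features

    result = generate_cohort(CohortConfig(seed=0, n_patients=150))
    table = extract_features(result.arcs, qa_records=result.qa_records)
    assert not table.failures
    return table.frame
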