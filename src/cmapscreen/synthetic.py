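"""Synthetic cohorts and compendia with planted ground truth.

Everything here is a pure function of its seed: one master seed fans out to
per-component child seeds via ``numpy.random.SeedSequence([seed, stream])``
so the cohort generator, the compendium generator and any replicate cohorts
draw from independent, reproducible streams.

Cohorts are two-group log-normal-noise matrices with planted up/down probes
of a stated log2 effect size.  Compendium instances are rank profiles built
from latent standard-normal draws; "reverser" drugs shift the planted up
probes down and the planted down probes up by their strength (mimickers do
the opposite), so a matched signature scores them with negative enrichment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import CASE, CONTROL, ExpressionMatrix
from .connectivity import RankedProfile, ReferenceCompendium

__all__ = [
    "CohortTruth",
    "CompendiumTruth",
    "probe_ids",
    "default_cohort_truth",
    "default_compendium_truth",
    "make_cohort",
    "make_compendium",
    "truth_to_json",
]

# child-seed stream tags (documented fan-out scheme)
_STREAM_BASELINE = 0
_STREAM_CONTROL = 1
_STREAM_CASE = 2
_STREAM_COMPENDIUM = 3


def probe_ids(n_probes: int) -> list[str]:
    """Canonical synthetic probe universe: P00000, P00001, ..."""
    return [f"P{i:05d}" for i in range(n_probes)]


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of one synthetic cohort."""

    planted_up: tuple[str, ...]
    planted_down: tuple[str, ...]
    effect_log2: float = 3.0
    sigma: float = 0.3
    n_case: int = 20
    n_control: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if set(self.planted_up) & set(self.planted_down):
            raise ValidationError("planted up/down sets must be disjoint")
        if self.effect_log2 < 0:
            raise ValidationError("effect_log2 must be >= 0")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass(frozen=True)
class CompendiumTruth:
    """Ground truth of one synthetic reference compendium."""

    reversers: dict[str, float] = field(default_factory=dict)
    mimickers: dict[str, float] = field(default_factory=dict)
    n_drugs: int = 40
    instances_per_drug: int = 5
    seed: int = 7

    def __post_init__(self) -> None:
        overlap = set(self.reversers) & set(self.mimickers)
        if overlap:
            raise ValidationError(
                f"reverser/mimicker sets must be disjoint: {sorted(overlap)}"
            )
        for name, s in {**self.reversers, **self.mimickers}.items():
            if s <= 0:
                raise ValidationError(f"strength for {name!r} must be > 0")
        if len(self.reversers) + len(self.mimickers) > self.n_drugs:
            raise ValidationError("more special drugs than n_drugs")

    @property
    def drug_names(self) -> list[str]:
        """Deterministic drug roster: reversers, mimickers, then nulls."""
        special = sorted(self.reversers) + sorted(self.mimickers)
        n_null = self.n_drugs - len(special)
        return special + [f"null{i:03d}" for i in range(n_null)]


def default_cohort_truth(
    n_probes: int = 2000,
    n_up: int = 100,
    n_down: int = 100,
    effect_log2: float = 3.0,
    sigma: float = 0.3,
    n_case: int = 20,
    n_control: int = 10,
    seed: int = 1,
) -> CohortTruth:
    """Desk-scale default: 2000 probes, first 100 up / next 100 down planted."""
    ids = probe_ids(n_probes)
    if n_up + n_down > n_probes:
        raise ValidationError("planted sets exceed probe universe")
    return CohortTruth(
        planted_up=tuple(ids[:n_up]),
        planted_down=tuple(ids[n_up : n_up + n_down]),
        effect_log2=effect_log2,
        sigma=sigma,
        n_case=n_case,
        n_control=n_control,
        seed=seed,
    )


def default_compendium_truth(
    n_drugs: int = 40,
    instances_per_drug: int = 5,
    n_reversers: int = 4,
    n_mimickers: int = 0,
    strength: float = 2.0,
    seed: int = 7,
) -> CompendiumTruth:
    reversers = {f"rev{i:02d}": strength for i in range(n_reversers)}
    mimickers = {f"mim{i:02d}": strength for i in range(n_mimickers)}
    return CompendiumTruth(
        reversers=reversers,
        mimickers=mimickers,
        n_drugs=n_drugs,
        instances_per_drug=instances_per_drug,
        seed=seed,
    )


def make_cohort(
    truth: CohortTruth, n_probes: int = 2000
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Simulate a labelled two-group log2 expression matrix.

    Per probe, a baseline is drawn from Uniform[4, 12]; control samples add
    Normal(0, sigma) noise; case samples additionally shift planted-up
    probes by +effect_log2 and planted-down probes by -effect_log2.
    """
    ids = probe_ids(n_probes)
    id_set = set(ids)
    for side, planted in (("up", truth.planted_up), ("down", truth.planted_down)):
        extra = set(planted) - id_set
        if extra:
            raise ValidationError(
                f"planted {side} probes outside the first {n_probes} ids: "
                f"{sorted(extra)[:5]}"
            )
    rng_base = np.random.default_rng(
        np.random.SeedSequence([truth.seed, _STREAM_BASELINE])
    )
    rng_ctrl = np.random.default_rng(
        np.random.SeedSequence([truth.seed, _STREAM_CONTROL])
    )
    rng_case = np.random.default_rng(
        np.random.SeedSequence([truth.seed, _STREAM_CASE])
    )
    baseline = rng_base.uniform(4.0, 12.0, size=n_probes)
    index = {p: i for i, p in enumerate(ids)}
    shift = np.zeros(n_probes)
    shift[[index[p] for p in truth.planted_up]] = truth.effect_log2
    shift[[index[p] for p in truth.planted_down]] = -truth.effect_log2

    ctrl = baseline[:, None] + rng_ctrl.normal(
        0.0, truth.sigma, size=(n_probes, truth.n_control)
    )
    case = (baseline + shift)[:, None] + rng_case.normal(
        0.0, truth.sigma, size=(n_probes, truth.n_case)
    )
    case_ids = [f"case{i:03d}" for i in range(truth.n_case)]
    ctrl_ids = [f"ctrl{i:03d}" for i in range(truth.n_control)]
    values = pd.DataFrame(
        np.hstack([case, ctrl]), index=ids, columns=case_ids + ctrl_ids
    )
    values.index.name = "probe_id"
    labels = {s: CASE for s in case_ids} | {s: CONTROL for s in ctrl_ids}
    return ExpressionMatrix(values, labels), truth


def make_compendium(
    cohort_truth: CohortTruth,
    comp_truth: CompendiumTruth,
    n_probes: int = 2000,
) -> tuple[ReferenceCompendium, CompendiumTruth]:
    """Simulate a rank-profile compendium with planted reversers/mimickers.

    Each instance draws a latent Normal(0, 1) value per probe; reverser
    instances subtract their strength on the cohort's planted-up probes and
    add it on the planted-down probes (mimickers mirrored).  The profile
    ordering is by descending latent value, so rank 1 is the probe most
    up-regulated by the treatment.
    """
    ids = probe_ids(n_probes)
    index = {p: i for i, p in enumerate(ids)}
    up_idx = [index[p] for p in cohort_truth.planted_up if p in index]
    down_idx = [index[p] for p in cohort_truth.planted_down if p in index]
    rng = np.random.default_rng(
        np.random.SeedSequence([comp_truth.seed, _STREAM_COMPENDIUM])
    )
    probes = np.asarray(ids, dtype=object)
    instances = []
    for drug in comp_truth.drug_names:
        strength = 0.0
        if drug in comp_truth.reversers:
            strength = -comp_truth.reversers[drug]
        elif drug in comp_truth.mimickers:
            strength = comp_truth.mimickers[drug]
        for k in range(comp_truth.instances_per_drug):
            z = rng.standard_normal(n_probes)
            if strength != 0.0:
                z[up_idx] += strength
                z[down_idx] -= strength
            # stable sort on -z: ties (absent a.s.) break by probe id order
            order = np.argsort(-z, kind="mergesort")
            instances.append(
                RankedProfile(
                    instance_id=f"{drug}_i{k:02d}",
                    drug=drug,
                    ordering=tuple(probes[order]),
                )
            )
    return ReferenceCompendium(ids, instances), comp_truth


def truth_to_json(
    cohort_truths: dict[str, CohortTruth],
    comp_truth: CompendiumTruth,
    path: str | Path,
) -> None:
    """Serialize ground truth (for provenance alongside simulated files)."""
    payload = {
        "cohorts": {
            cid: dataclasses.asdict(t) for cid, t in sorted(cohort_truths.items())
        },
        "compendium": dataclasses.asdict(comp_truth),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
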