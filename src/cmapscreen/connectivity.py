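"""KS connectivity scoring of a signature against a rank-profile compendium.

Each compendium instance is one drug-treatment profile represented as a
complete rank ordering of the probe universe (position 1 = most up-regulated
by treatment).  Scoring proceeds in four steps:

1. per-instance KS tag statistics for the up and the down tag list,
2. the combined enrichment ``es = ks_up - ks_down`` (zero when both KS
   values share a sign),
3. scaling of instance scores into [-1, 1] by the extreme positive/negative
   es values,
4. a drug-level KS enrichment over the scaled-score ordering, with an exact
   or seeded Monte-Carlo p-value under the random-position null.

A drug is a hit when its enrichment is negative and its p-value is below
the retention threshold (default 0.05).
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .signature import Signature

__all__ = [
    "RankedProfile",
    "ReferenceCompendium",
    "InstanceScore",
    "DrugResult",
    "ConnectivityResult",
    "ks_tag_score",
    "instance_es",
    "scale_scores",
    "drug_enrichment",
    "drug_p_value",
    "query",
    "read_compendium",
    "write_compendium",
    "write_drug_gmt",
]

EXACT_LIMIT = 1_000_000  #: max C(n, t) for exhaustive p-value enumeration


# ---------------------------------------------------------------------------
# KS statistic


def _validate_positions(positions: np.ndarray, n: int) -> None:
    if positions.size == 0:
        raise ValidationError("empty tag position set")
    if np.any(positions[1:] <= positions[:-1]):
        raise ValidationError("tag positions must be strictly increasing")
    if positions[0] < 1 or positions[-1] > n:
        raise ValidationError(f"tag positions must lie in 1..{n}")


def ks_tag_score(tag_positions: Sequence[int], n: int) -> float:
    """Signed KS statistic for a tag set at ascending positions in 1..n.

    With ``V(1) < ... < V(t)`` the two one-sided deviations are
    ``a = max_j [ j/t - V(j)/n ]`` and ``b = max_j [ V(j)/n - (j-1)/t ]``;
    the score is ``a`` if ``a > b`` else ``-b``.  Positive scores mean the
    tags cluster at the top of the ranking, negative at the bottom.
    """
    V = np.asarray(tag_positions, dtype=float)
    _validate_positions(V, n)
    t = V.size
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - V / n)
    b = np.max(V / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def _ks_rows(positions: np.ndarray, n: int) -> np.ndarray:
    """Vectorized :func:`ks_tag_score` over rows of ascending positions."""
    m, t = positions.shape
    j = np.arange(1, t + 1, dtype=float)
    V = positions / n
    a = (j / t - V).max(axis=1)
    b = (V - (j - 1) / t).max(axis=1)
    return np.where(a > b, a, -b)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class RankedProfile:
    """One treatment instance: a complete probe ordering for one drug."""

    instance_id: str
    drug: str
    ordering: tuple[str, ...]  # position 1 first


class ReferenceCompendium:
    """Instances (drug, rank profile) over a shared probe universe."""

    def __init__(self, probe_universe: Sequence[str], instances: Iterable[RankedProfile]):
        self.probe_universe: list[str] = list(probe_universe)
        if len(set(self.probe_universe)) != len(self.probe_universe):
            raise ValidationError("probe universe contains duplicates")
        self.instances: list[RankedProfile] = list(instances)
        if not self.instances:
            raise ValidationError("compendium has no instances")
        ids = [inst.instance_id for inst in self.instances]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate instance ids in compendium")
        universe = frozenset(self.probe_universe)
        for inst in self.instances:
            if len(inst.ordering) != len(universe) or frozenset(inst.ordering) != universe:
                raise ValidationError(
                    f"instance {inst.instance_id!r} is not a permutation of "
                    "the probe universe"
                )
        self._probe_index = {p: i for i, p in enumerate(self.probe_universe)}
        self._rank_matrix: np.ndarray | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_universe)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def drug_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for inst in self.instances:
            idx.setdefault(inst.drug, []).append(inst.instance_id)
        return idx

    @property
    def drugs(self) -> list[str]:
        return sorted(self.drug_index)

    def rank_matrix(self) -> np.ndarray:
        """(n_instances, n_probes) array: 1-based rank of each universe probe."""
        if self._rank_matrix is None:
            n = self.n_probes
            mat = np.empty((self.n_instances, n), dtype=np.int32)
            for i, inst in enumerate(self.instances):
                cols = np.fromiter(
                    (self._probe_index[p] for p in inst.ordering),
                    dtype=np.int64,
                    count=n,
                )
                mat[i, cols] = np.arange(1, n + 1, dtype=np.int32)
            self._rank_matrix = mat
        return self._rank_matrix

    def probe_indices(self, probes: Iterable[str]) -> np.ndarray:
        return np.fromiter(
            (self._probe_index[p] for p in probes if p in self._probe_index),
            dtype=np.int64,
        )


@dataclass(frozen=True)
class InstanceScore:
    instance_id: str
    drug: str
    ks_up: float | None
    ks_down: float | None
    es: float
    scaled_score: float = 0.0


@dataclass(frozen=True)
class DrugResult:
    drug: str
    n_instances: int
    enrichment: float
    p_value: float
    hit: bool


@dataclass
class ConnectivityResult:
    signature_name: str
    instance_scores: list[InstanceScore]
    drug_results: list[DrugResult]
    rng_seed: int | None
    n_permutations: int
    p_mode: str
    dropped_up_tags: int = 0
    dropped_down_tags: int = 0
    p_threshold: float = 0.05

    @property
    def hits(self) -> list[str]:
        return [d.drug for d in self.drug_results if d.hit]

    def instances_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "instance_id": s.instance_id,
                    "drug": s.drug,
                    "ks_up": s.ks_up,
                    "ks_down": s.ks_down,
                    "es": s.es,
                    "score": s.scaled_score,
                }
                for s in self.instance_scores
            ]
        )

    def drugs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug": d.drug,
                    "n_instances": d.n_instances,
                    "enrichment": d.enrichment,
                    "p_value": d.p_value,
                    "hit": d.hit,
                }
                for d in self.drug_results
            ]
        )


# ---------------------------------------------------------------------------
# Scoring operations


def _combine_es(ks_up: float | None, ks_down: float | None) -> float:
    if ks_up is None and ks_down is None:
        raise ValidationError("signature contributed no tags")
    if ks_down is None:
        return float(ks_up)
    if ks_up is None:
        return float(-ks_down)
    su, sd = np.sign(ks_up), np.sign(ks_down)
    if su == sd and su != 0:
        return 0.0
    return float(ks_up - ks_down)


def instance_es(
    signature: Signature, profile: RankedProfile, universe: Sequence[str] | None = None
) -> InstanceScore:
    """Score one instance: per-side KS plus the combined enrichment.

    Tags absent from the profile's universe are dropped; a side present in
    the signature that loses all of its tags raises.  For an up-only
    signature ``es = ks_up``; down-only gives ``es = -ks_down``.
    """
    ordering = profile.ordering
    n = len(ordering)
    pos = {p: i + 1 for i, p in enumerate(ordering)}

    def side_positions(tags: list[str], side: str) -> np.ndarray | None:
        if not tags:
            return None
        kept = sorted(pos[t] for t in tags if t in pos)
        if not kept:
            raise ValidationError(
                f"no {side} tags survive intersection with the probe universe"
            )
        return np.asarray(kept)

    up_pos = side_positions(signature.up_tags, "up")
    down_pos = side_positions(signature.down_tags, "down")
    ks_up = ks_tag_score(up_pos, n) if up_pos is not None else None
    ks_down = ks_tag_score(down_pos, n) if down_pos is not None else None
    return InstanceScore(
        instance_id=profile.instance_id,
        drug=profile.drug,
        ks_up=ks_up,
        ks_down=ks_down,
        es=_combine_es(ks_up, ks_down),
    )


def scale_scores(es_values: Sequence[float]) -> np.ndarray:
    """Scale instance es values into [-1, 1].

    ``p`` is the largest positive es and ``q`` the magnitude of the most
    negative; positive values divide by ``p``, negative by ``q``, zeros map
    to zero.
    """
    es = np.asarray(es_values, dtype=float)
    if es.size == 0:
        raise ValidationError("need at least one instance to scale")
    scaled = np.zeros_like(es)
    pos = es > 0
    neg = es < 0
    if pos.any():
        scaled[pos] = es[pos] / es[pos].max()
    if neg.any():
        scaled[neg] = es[neg] / abs(es[neg].min())
    return scaled


def drug_enrichment(
    ordered_instances: Sequence[str], member_ids: Iterable[str]
) -> float:
    """KS enrichment of a drug's instances within the score-ordered list."""
    members = set(member_ids)
    if not members:
        raise ValidationError("drug has no instances")
    index = {inst: i + 1 for i, inst in enumerate(ordered_instances)}
    missing = members - index.keys()
    if missing:
        raise ValidationError(f"member instances not in ordering: {sorted(missing)}")
    positions = sorted(index[m] for m in members)
    return ks_tag_score(positions, len(ordered_instances))


def _null_subset_scores_exact(n: int, t: int) -> np.ndarray:
    total = comb(n, t)
    if total > EXACT_LIMIT:
        raise ValidationError(
            f"exact mode infeasible: C({n},{t}) = {total} > {EXACT_LIMIT}"
        )
    subsets = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(1, n + 1), t)),
        dtype=np.int64,
        count=total * t,
    ).reshape(total, t)
    return _ks_rows(subsets, n)


def _null_subset_scores_mc(
    n: int, t: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    # random t-subsets of 1..n via row-wise partial argsort of uniforms
    u = rng.random((n_perm, n))
    picks = np.argpartition(u, t - 1, axis=1)[:, :t] + 1
    picks.sort(axis=1)
    return _ks_rows(picks, n)


def _p_from_null(observed: float, null_scores: np.ndarray, mc: bool) -> float:
    if observed <= 0:
        extreme = int(np.sum(null_scores <= observed))
    else:
        extreme = int(np.sum(null_scores >= observed))
    if mc:
        return (1 + extreme) / (null_scores.size + 1)
    return extreme / null_scores.size


def drug_p_value(
    observed: float,
    n: int,
    t: int,
    mode: str = "exact",
    n_perm: int = 10_000,
    seed: int | None = None,
    null_scores: np.ndarray | None = None,
) -> float:
    """One-sided p-value of a drug enrichment under the random-subset null.

    ``exact`` enumerates every C(n, t) position subset (requires
    C(n, t) <= 1e6) and reports the fraction at least as extreme in the
    observed direction.  ``permutation`` draws ``n_perm`` seeded random
    subsets and reports ``(1 + extreme) / (n_perm + 1)``.
    """
    if t < 1 or t > n:
        raise ValidationError(f"member count {t} out of range 1..{n}")
    if mode == "exact":
        if null_scores is None:
            null_scores = _null_subset_scores_exact(n, t)
        return _p_from_null(observed, null_scores, mc=False)
    if mode == "permutation":
        if n_perm < 100:
            raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
        if null_scores is None:
            rng = np.random.default_rng(seed)
            null_scores = _null_subset_scores_mc(n, t, n_perm, rng)
        return _p_from_null(observed, null_scores, mc=True)
    raise ValidationError(f"unknown p-value mode {mode!r}")


def _tie_key(seed: int | None, instance_id: str) -> int:
    digest = hashlib.blake2b(
        f"{0 if seed is None else seed}:{instance_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big")


def query(
    signature: Signature,
    compendium: ReferenceCompendium,
    n_perm: int = 10_000,
    seed: int | None = 0,
    p_threshold: float = 0.05,
    p_mode: str = "auto",
) -> ConnectivityResult:
    """Run the full connectivity screen of a signature against a compendium.

    Scores every instance, scales, orders by scaled score descending (ties
    broken by instance id), computes per-drug enrichment and p-value, and
    flags hits (negative enrichment, p below threshold).  ``p_mode`` is
    ``auto`` (exact when C(n, t) <= 1e6, else Monte Carlo), ``exact`` or
    ``permutation``.  Monte-Carlo null score sets are derived from ``seed``
    per member-count, so results do not depend on drug iteration order.
    """
    if p_mode not in ("auto", "exact", "permutation"):
        raise ValidationError(f"unknown p-value mode {p_mode!r}")
    universe = set(compendium.probe_universe)
    up_kept = [p for p in signature.up_tags if p in universe]
    down_kept = [p for p in signature.down_tags if p in universe]
    dropped_up = len(signature.up_tags) - len(up_kept)
    dropped_down = len(signature.down_tags) - len(down_kept)
    if signature.up_tags and not up_kept:
        raise ValidationError("no up tags survive the compendium universe")
    if signature.down_tags and not down_kept:
        raise ValidationError("no down tags survive the compendium universe")
    if not up_kept and not down_kept:
        raise ValidationError("signature has no tags in the compendium universe")

    ranks = compendium.rank_matrix()
    n = compendium.n_probes

    def side_ks(tags: list[str]) -> np.ndarray | None:
        if not tags:
            return None
        cols = compendium.probe_indices(tags)
        pos = np.sort(ranks[:, cols], axis=1)
        return _ks_rows(pos, n)

    ks_up = side_ks(up_kept)
    ks_down = side_ks(down_kept)
    m = compendium.n_instances
    es = np.empty(m)
    for i in range(m):
        es[i] = _combine_es(
            None if ks_up is None else float(ks_up[i]),
            None if ks_down is None else float(ks_down[i]),
        )
    scaled = scale_scores(es)

    scores = [
        InstanceScore(
            instance_id=inst.instance_id,
            drug=inst.drug,
            ks_up=None if ks_up is None else float(ks_up[i]),
            ks_down=None if ks_down is None else float(ks_down[i]),
            es=float(es[i]),
            scaled_score=float(scaled[i]),
        )
        for i, inst in enumerate(compendium.instances)
    ]
    # Tied scaled scores are frequent (the same-sign rule zeroes roughly half
    # of all null instances), and a drug's instance ids share a prefix, so a
    # lexicographic tie-break would seat them adjacently and manufacture
    # spurious drug enrichment.  Break ties by a seeded keyed hash instead:
    # deterministic for a given seed, exchangeable under the null.
    scores.sort(
        key=lambda s: (-s.scaled_score, _tie_key(seed, s.instance_id), s.instance_id)
    )
    ordering = [s.instance_id for s in scores]

    null_cache: dict[int, tuple[np.ndarray, bool]] = {}

    def null_for(t: int) -> tuple[np.ndarray, bool]:
        if t not in null_cache:
            exact_ok = comb(m, t) <= EXACT_LIMIT
            if p_mode == "exact" and not exact_ok:
                raise ValidationError(
                    f"exact mode infeasible: C({m},{t}) > {EXACT_LIMIT}"
                )
            if p_mode == "exact" or (p_mode == "auto" and exact_ok):
                null_cache[t] = (_null_subset_scores_exact(m, t), False)
            else:
                if n_perm < 100:
                    raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
                rng = np.random.default_rng(
                    np.random.SeedSequence([0 if seed is None else seed, t])
                )
                null_cache[t] = (_null_subset_scores_mc(m, t, n_perm, rng), True)
        return null_cache[t]

    drug_results = []
    for drug in compendium.drugs:
        members = compendium.drug_index[drug]
        enr = drug_enrichment(ordering, members)
        null_scores, mc = null_for(len(members))
        p = _p_from_null(enr, null_scores, mc=mc)
        drug_results.append(
            DrugResult(
                drug=drug,
                n_instances=len(members),
                enrichment=enr,
                p_value=p,
                hit=bool(enr < 0 and p < p_threshold),
            )
        )

    used_modes = {mc for _, mc in null_cache.values()}
    mode_label = p_mode
    if p_mode == "auto":
        mode_label = "permutation" if used_modes == {True} else (
            "exact" if used_modes == {False} else "mixed"
        )
    return ConnectivityResult(
        signature_name=signature.name,
        instance_scores=scores,
        drug_results=drug_results,
        rng_seed=seed,
        n_permutations=n_perm,
        p_mode=mode_label,
        dropped_up_tags=dropped_up,
        dropped_down_tags=dropped_down,
        p_threshold=p_threshold,
    )


# ---------------------------------------------------------------------------
# Compendium I/O


def read_compendium(
    ranks_path: str | Path, instances_path: str | Path
) -> ReferenceCompendium:
    """Read a compendium from a ranks TSV plus an instance-metadata TSV.

    The ranks table has a ``probe_id`` column and one integer column per
    instance (rank 1..n, 1 = most up-regulated); the metadata table has
    columns ``instance_id`` and ``drug`` (extras such as cell_line/dose are
    carried along but unused).
    """
    ranks = pd.read_csv(ranks_path, sep="\t")
    if ranks.columns.empty or ranks.columns[0] != "probe_id":
        raise FormatError(f"{ranks_path}: first column must be 'probe_id'")
    ranks = ranks.set_index("probe_id")
    ranks.index = ranks.index.astype(str)
    meta = pd.read_csv(instances_path, sep="\t", dtype=str)
    for col in ("instance_id", "drug"):
        if col not in meta.columns:
            raise FormatError(f"{instances_path}: missing column {col!r}")
    drug_of = dict(zip(meta["instance_id"], meta["drug"]))
    missing = [c for c in ranks.columns if c not in drug_of]
    if missing:
        raise ValidationError(
            f"instances in ranks table without metadata: {missing}"
        )
    universe = list(ranks.index)
    n = len(universe)
    probes = np.asarray(universe, dtype=object)
    instances = []
    for inst_id in ranks.columns:
        col = ranks[inst_id].to_numpy()
        r = col.astype(np.int64)
        if np.any(r != col) or sorted(r) != list(range(1, n + 1)):
            raise ValidationError(
                f"{ranks_path}: column {inst_id!r} is not a 1..{n} rank permutation"
            )
        ordering = np.empty(n, dtype=object)
        ordering[r - 1] = probes
        instances.append(
            RankedProfile(
                instance_id=str(inst_id),
                drug=str(drug_of[inst_id]),
                ordering=tuple(ordering),
            )
        )
    return ReferenceCompendium(universe, instances)


def write_compendium(
    compendium: ReferenceCompendium,
    ranks_path: str | Path,
    instances_path: str | Path,
) -> None:
    pos = {p: i for i, p in enumerate(compendium.probe_universe)}
    data = {"probe_id": compendium.probe_universe}
    for inst in compendium.instances:
        col = np.empty(compendium.n_probes, dtype=np.int64)
        for rank, probe in enumerate(inst.ordering, start=1):
            col[pos[probe]] = rank
        data[inst.instance_id] = col
    pd.DataFrame(data).to_csv(ranks_path, sep="\t", index=False)
    meta = pd.DataFrame(
        [{"instance_id": i.instance_id, "drug": i.drug} for i in compendium.instances]
    )
    meta.to_csv(instances_path, sep="\t", index=False)


def write_drug_gmt(compendium: ReferenceCompendium, path: str | Path) -> None:
    """Export per-drug instance sets as GMT (name, description, members)."""
    with open(path, "w", encoding="utf-8") as fh:
        for drug in compendium.drugs:
            members = "\t".join(compendium.drug_index[drug])
            fh.write(f"{drug}\tna\t{members}\n")
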