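"""Up/down probe signature extraction by volcano selection.

A probe enters the signature when it passes both a pooled-variance two-sample
t-test p-value threshold and a fold-change threshold measured as the
difference of group means on the log2 scale.  Defaults are P < 1e-4 and a
fourfold change (inclusive boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .expression import CASE, CONTROL, ExpressionMatrix

__all__ = [
    "TTestResult",
    "Signature",
    "two_sample_t",
    "passes_fold",
    "select_signature",
    "write_grp",
    "read_grp",
    "write_signature",
    "read_signature",
]

STATS_COLUMNS = ["probe_id", "mean_case", "mean_control", "delta_log2", "t", "p"]


class TTestResult(NamedTuple):
    t: float
    p: float
    #: True when both groups have zero variance but different means; the
    #: pooled t is then unbounded and p is reported as 0.
    degenerate: bool


def two_sample_t(case_values, control_values) -> TTestResult:
    """Pooled-variance Student t-test, two-sided, df = n1 + n2 - 2.

    Both groups need at least two observations.  If both groups have zero
    variance the test degenerates: equal means give ``(t=0, p=1)``; unequal
    means give ``p=0`` with the ``degenerate`` flag set.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError(
            f"each group needs >=2 values, got {x.size} and {y.size}"
        )
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    delta = x.mean() - y.mean()
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if delta == 0.0:
            return TTestResult(0.0, 1.0, False)
        return TTestResult(math.copysign(math.inf, delta), 0.0, True)
    t = delta / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(min(p, 1.0)), False)


def passes_fold(
    delta_log2: float, fold_threshold: float, inclusive: bool = True
) -> bool:
    """True when |log2 fold change| reaches the linear fold threshold.

    The boundary is inclusive by default ("at least" a given fold); pass
    ``inclusive=False`` for a strict reading.
    """
    if fold_threshold <= 1:
        raise ValidationError(f"fold_threshold must be > 1, got {fold_threshold}")
    cut = math.log2(fold_threshold)
    mag = abs(delta_log2)
    return mag >= cut if inclusive else mag > cut


@dataclass
class Signature:
    """Ordered up/down tag lists plus the full per-probe statistics table.

    ``up_tags`` and ``down_tags`` are sorted by |t| descending (ties broken
    by probe id); ``stats`` covers every probe tested with columns
    ``probe_id, mean_case, mean_control, delta_log2, t, p``.
    """

    up_tags: list[str]
    down_tags: list[str]
    stats: pd.DataFrame = field(repr=False)
    p_threshold: float = 1e-4
    fold_threshold: float = 4.0
    name: str = "signature"

    def __post_init__(self) -> None:
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise ValidationError(f"up/down tag lists overlap: {sorted(overlap)}")

    @property
    def is_empty(self) -> bool:
        return not self.up_tags and not self.down_tags

    @property
    def n_up(self) -> int:
        return len(self.up_tags)

    @property
    def n_down(self) -> int:
        return len(self.down_tags)


def _ordered_tags(mask: np.ndarray, probes: np.ndarray, abs_t: np.ndarray) -> list[str]:
    picked = np.flatnonzero(mask)
    ranked = sorted(picked, key=lambda i: (-abs_t[i], probes[i]))
    return [str(probes[i]) for i in ranked]


def select_signature(
    matrix: ExpressionMatrix,
    p_threshold: float = 1e-4,
    fold_threshold: float = 4.0,
    inclusive: bool = True,
    name: str = "signature",
) -> Signature:
    """Volcano selection of up/down tags from a labelled log2 matrix.

    Up tags satisfy ``p < p_threshold`` and ``delta_log2 >= +log2(fold)``;
    down tags mirror with ``<= -log2(fold)`` (strict inequalities on the fold
    boundary when ``inclusive`` is false).  An empty result is returned, not
    raised.
    """
    if not (0 < p_threshold <= 1):
        raise ValidationError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if fold_threshold <= 1:
        raise ValidationError(f"fold_threshold must be > 1, got {fold_threshold}")
    case_ids = matrix.group_samples(CASE)
    ctrl_ids = matrix.group_samples(CONTROL)
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValidationError(
            f"both groups need >=2 samples, got {len(case_ids)} case / "
            f"{len(ctrl_ids)} control"
        )
    X = matrix.values[case_ids].to_numpy(dtype=float)
    Y = matrix.values[ctrl_ids].to_numpy(dtype=float)
    n1, n2 = X.shape[1], Y.shape[1]
    df = n1 + n2 - 2
    m1 = X.mean(axis=1)
    m2 = Y.mean(axis=1)
    delta = m1 - m2
    sp2 = ((n1 - 1) * X.var(axis=1, ddof=1) + (n2 - 1) * Y.var(axis=1, ddof=1)) / df

    t = np.zeros_like(delta)
    p = np.ones_like(delta)
    ok = sp2 > 0
    se = np.sqrt(sp2[ok] * (1.0 / n1 + 1.0 / n2))
    t[ok] = delta[ok] / se
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df)
    # degenerate zero-variance probes with separated means
    degen = (~ok) & (delta != 0)
    t[degen] = np.sign(delta[degen]) * np.inf
    p[degen] = 0.0
    np.clip(p, 0.0, 1.0, out=p)

    probes = np.asarray(matrix.probe_ids, dtype=object)
    stats = pd.DataFrame(
        {
            "probe_id": probes,
            "mean_case": m1,
            "mean_control": m2,
            "delta_log2": delta,
            "t": t,
            "p": p,
        }
    )
    cut = math.log2(fold_threshold)
    sig = p < p_threshold
    if inclusive:
        up = sig & (delta >= cut)
        down = sig & (delta <= -cut)
    else:
        up = sig & (delta > cut)
        down = sig & (delta < -cut)
    abs_t = np.abs(t)
    return Signature(
        up_tags=_ordered_tags(up, probes, abs_t),
        down_tags=_ordered_tags(down, probes, abs_t),
        stats=stats,
        p_threshold=p_threshold,
        fold_threshold=fold_threshold,
        name=name,
    )


# ---------------------------------------------------------------------------
# Serialization: GRP tag lists + stats TSV


def write_grp(tags, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tag in tags:
            fh.write(f"{tag}\n")


def read_grp(path: str | Path) -> list[str]:
    tags = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tag = line.split("#", 1)[0].strip()
            if tag:
                tags.append(tag)
    return tags


def write_signature(signature: Signature, outdir: str | Path) -> dict[str, Path]:
    """Write ``<name>_up.grp``, ``<name>_dn.grp`` and ``<name>_stats.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "up": outdir / f"{signature.name}_up.grp",
        "down": outdir / f"{signature.name}_dn.grp",
        "stats": outdir / f"{signature.name}_stats.tsv",
    }
    write_grp(signature.up_tags, paths["up"])
    write_grp(signature.down_tags, paths["down"])
    signature.stats.to_csv(
        paths["stats"], sep="\t", index=False, float_format="%.10g"
    )
    return paths


def read_signature(
    up_path: str | Path,
    down_path: str | Path,
    stats_path: str | Path | None = None,
    name: str = "signature",
) -> Signature:
    stats = (
        pd.read_csv(stats_path, sep="\t")
        if stats_path is not None
        else pd.DataFrame(columns=STATS_COLUMNS)
    )
    return Signature(
        up_tags=read_grp(up_path),
        down_tags=read_grp(down_path),
        stats=stats,
        name=name,
    )
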