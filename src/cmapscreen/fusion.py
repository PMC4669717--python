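"""Multi-cohort fusion of drug hit lists and functional-category annotation.

Fusion is the union of per-cohort hit sets with per-drug support counts and
exact-membership Venn region sizes; it is deliberately not an intersection.
Drug names are normalized (lower-cased, trimmed) before any set operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CATEGORIES",
    "DEFAULT_CATEGORY_MAP",
    "CohortHits",
    "FusionResult",
    "normalize_drug",
    "fuse",
    "annotate",
    "read_cohort_hits",
    "read_category_map",
    "write_fusion",
]

CATEGORIES = (
    "anti-inflammation",
    "antibiotics",
    "antipsychotics",
    "cardiovascular",
    "chemotherapeutic",
    "others",
    "unknown",
)

#: Static functional-category map for the screen's validated drug panel.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "tanespimycin": "anti-inflammation",
    "15-delta prostaglandin j2": "anti-inflammation",
    "luteolin": "anti-inflammation",
    "parthenolide": "anti-inflammation",
    "thiostrepton": "antibiotics",
    "antimycin a": "antibiotics",
    "sulconazole": "antibiotics",
    "cycloserine": "antibiotics",
    "chlorpromazine": "antipsychotics",
    "trifluoperazine": "antipsychotics",
    "thioridazine": "antipsychotics",
    "prochlorperazine": "antipsychotics",
    "fluphenazine": "antipsychotics",
    "perphenazine": "antipsychotics",
    "piperlongumine": "cardiovascular",
    "propafenone": "cardiovascular",
    "phenoxybenzamine": "cardiovascular",
    "amiodarone": "cardiovascular",
    "daunorubicin": "chemotherapeutic",
    "camptothecin": "chemotherapeutic",
    "thioguanosine": "chemotherapeutic",
    "8-azaguanine": "chemotherapeutic",
    "gw-8510": "chemotherapeutic",
    "ellipticine": "chemotherapeutic",
    "cloperastine": "others",
    "nitrarine dihydrochloride": "others",
    "emetine": "others",
    "tyloxapol": "others",
    "norcyclobenzaprine": "others",
    "trichostatin a": "others",
    "pyrvinium": "others",
    "bepridil": "others",
    "verteporfin": "others",
    "vorinostat": "others",
}


def normalize_drug(name: str) -> str:
    return name.strip().lower()


@dataclass(frozen=True)
class CohortHits:
    """Hit drugs (negative enrichment, significant p) from one cohort."""

    cohort_id: str
    hits: frozenset[str]

    @classmethod
    def from_names(cls, cohort_id: str, names: Iterable[str]) -> "CohortHits":
        return cls(cohort_id, frozenset(normalize_drug(n) for n in names))


@dataclass
class FusionResult:
    cohort_ids: list[str]
    union_drugs: set[str]
    support: dict[str, int]
    venn_regions: dict[frozenset, int] = field(repr=False)

    @property
    def n_union(self) -> int:
        return len(self.union_drugs)

    def region_table(self) -> pd.DataFrame:
        rows = []
        for subset, count in self.venn_regions.items():
            label = "&".join(
                c for c in self.cohort_ids if c in subset
            )
            rows.append({"subset": label, "size": len(subset), "count": count})
        rows.sort(key=lambda r: (r["size"], r["subset"]))
        return pd.DataFrame(rows, columns=["subset", "size", "count"])


def fuse(hit_lists: Sequence[CohortHits]) -> FusionResult:
    """Union the cohort hit sets, with support counts and Venn regions.

    Venn regions cover all ``2^k - 1`` non-empty cohort subsets; a drug sits
    in the region of exactly the cohorts that hit it, so region counts sum
    to the union size.
    """
    if not hit_lists:
        raise ValidationError("need at least one cohort")
    ids = [h.cohort_id for h in hit_lists]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate cohort ids: {ids}")
    if len(ids) > 16:
        raise ValidationError("more than 16 cohorts: Venn regions intractable")
    union: set[str] = set().union(*(h.hits for h in hit_lists))
    membership = {
        d: frozenset(h.cohort_id for h in hit_lists if d in h.hits) for d in union
    }
    support = {d: len(m) for d, m in membership.items()}
    regions: dict[frozenset, int] = {}
    for k in range(1, len(ids) + 1):
        for subset in combinations(ids, k):
            regions[frozenset(subset)] = 0
    for m in membership.values():
        regions[m] += 1
    return FusionResult(
        cohort_ids=ids, union_drugs=union, support=support, venn_regions=regions
    )


def annotate(
    fusion: FusionResult, categories: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate union drugs with support and functional category.

    Drugs missing from the category map get ``unknown``.  Sorted by support
    descending, then drug id.
    """
    if categories is None:
        categories = DEFAULT_CATEGORY_MAP
    cat = {normalize_drug(k): v for k, v in categories.items()}
    bad = sorted(set(cat.values()) - set(CATEGORIES))
    if bad:
        raise ValidationError(f"unknown categories in map: {bad}")
    rows = [
        {
            "drug": d,
            "support": fusion.support[d],
            "category": cat.get(d, "unknown"),
        }
        for d in fusion.union_drugs
    ]
    rows.sort(key=lambda r: (-r["support"], r["drug"]))
    return pd.DataFrame(rows, columns=["drug", "support", "category"])


# ---------------------------------------------------------------------------
# I/O


def read_cohort_hits(
    path: str | Path,
    cohort_id: str | None = None,
    p_threshold: float = 0.05,
) -> CohortHits:
    """Read a per-cohort drug table and apply the retention rule.

    The TSV needs columns ``drug``, ``enrichment``, ``p_value`` (a ``hit``
    column, when present, is ignored in favour of re-applying the rule).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("drug", "enrichment", "p_value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    keep = df[(df["enrichment"] < 0) & (df["p_value"] < p_threshold)]
    cid = cohort_id if cohort_id is not None else Path(path).stem
    return CohortHits.from_names(cid, keep["drug"].astype(str))


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``drug<TAB>category`` map."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            drug, category = normalize_drug(parts[0]), parts[1].strip()
            if lineno == 1 and (parts[0], category) == ("drug", "category"):
                continue
            if category not in CATEGORIES:
                raise ValidationError(
                    f"{path}:{lineno}: unknown category {category!r}"
                )
            out[drug] = category
    return out


def write_fusion(
    fusion: FusionResult,
    annotated: pd.DataFrame,
    fusion_path: str | Path,
    venn_path: str | Path,
) -> None:
    annotated.to_csv(fusion_path, sep="\t", index=False)
    fusion.region_table().to_csv(venn_path, sep="\t", index=False)
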