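"""One-to-one resolution of cross-species homolog candidates.

Homology tables retrieved from genome databases frequently list several
candidate targets per query gene (one-to-many and many-to-many relations).
Candidates are ranked per query by a fixed priority cascade of orthology
scores and then assigned greedily so that every query and every target is
used at most once:

1. confidence score (higher better),
2. gene order conservation (GOC) score (higher better),
3. target %ID — fraction of the target sequence matching the query (higher
   better),
4. query %ID (higher better),
5. dN/dS ratio — by default values closest to 0 rank first, preferring pairs
   under purifying selection (set ``dnds_low_better=False`` to invert),
6. lexicographically smallest target id (deterministic tie-break).

A score missing at some cascade level ranks below every present value at
that level.  Queries whose candidates are all claimed by earlier queries
fall through to their next-ranked candidate; queries left without a free
target are reported as unmapped, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io import CANDIDATE_COLUMNS

_INF = math.inf


@dataclass(frozen=True)
class HomologCandidate:
    """A scored query→target homology candidate; missing scores are None."""

    query_id: str
    target_id: str
    confidence: float | None = None
    goc: float | None = None
    target_pid: float | None = None
    query_pid: float | None = None
    dn_ds: float | None = None

    def __post_init__(self) -> None:
        for name in ("goc", "target_pid", "query_pid"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] for {self.query_id}")
        if self.dn_ds is not None and self.dn_ds < 0:
            raise ValueError(f"dn_ds={self.dn_ds} negative for {self.query_id}")


@dataclass
class HomologyMap:
    """Resolved homology: an injective query→target mapping plus leftovers."""

    mapping: dict[str, str] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(set(targets)) != len(targets):
            raise ValueError("homology map is not injective on targets")

    def invert(self) -> "HomologyMap":
        """Target→query view of the mapping (valid because it is injective)."""
        return HomologyMap(
            mapping={t: q for q, t in self.mapping.items()}, unmapped=set()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.mapping.items()), columns=["query_id", "target_id"]
        )

    def __len__(self) -> int:
        return len(self.mapping)


def _none_if_nan(v) -> float | None:
    if v is None:
        return None
    try:
        if math.isnan(v):
            return None
    except TypeError:
        pass
    return float(v)


def candidates_from_frame(df: pd.DataFrame) -> list[HomologCandidate]:
    """Parse a candidate table (columns as in :data:`io.CANDIDATE_COLUMNS`)."""
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table lacks columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                HomologCandidate(
                    query_id=str(row.query_id),
                    target_id=str(row.target_id),
                    confidence=_none_if_nan(row.confidence),
                    goc=_none_if_nan(row.goc),
                    target_pid=_none_if_nan(row.target_pid),
                    query_pid=_none_if_nan(row.query_pid),
                    dn_ds=_none_if_nan(row.dn_ds),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed candidate row {i}: {exc}") from exc
    return out


def _cascade_key(c: HomologCandidate, dnds_low_better: bool) -> tuple:
    # ascending sort: negate "higher is better" scores; missing -> worst
    def desc(v: float | None) -> float:
        return -v if v is not None else _INF

    if c.dn_ds is None:
        dnds_key = _INF
    else:
        dnds_key = abs(c.dn_ds) if dnds_low_better else -c.dn_ds
    return (
        desc(c.confidence),
        desc(c.goc),
        desc(c.target_pid),
        desc(c.query_pid),
        dnds_key,
        c.target_id,
    )


def resolve_homologs(
    candidates: list[HomologCandidate] | pd.DataFrame,
    one_to_one: bool = True,
    dnds_low_better: bool = True,
) -> HomologyMap:
    """Resolve scored candidates to a deterministic homology map.

    Queries are processed in ascending id order (so the result does not
    depend on input row order); each takes its best-ranked candidate whose
    target is still free.  With ``one_to_one=False`` every query simply
    takes its best-ranked candidate, allowing many-to-one maps.

    Duplicate (query, target) rows collapse to the best-scoring record.
    """
    if isinstance(candidates, pd.DataFrame):
        candidates = candidates_from_frame(candidates)
    if not candidates:
        return HomologyMap()

    per_query: dict[str, list[HomologCandidate]] = {}
    for c in candidates:
        per_query.setdefault(c.query_id, []).append(c)

    ranked: dict[str, list[HomologCandidate]] = {}
    for q, cands in per_query.items():
        cands = sorted(cands, key=lambda c: _cascade_key(c, dnds_low_better))
        seen: set[str] = set()
        dedup = []
        for c in cands:  # best record per (query, target) survives
            if c.target_id not in seen:
                seen.add(c.target_id)
                dedup.append(c)
        ranked[q] = dedup

    mapping: dict[str, str] = {}
    unmapped: set[str] = set()
    taken: set[str] = set()
    for q in sorted(ranked):
        chosen = None
        for c in ranked[q]:
            if not one_to_one or c.target_id not in taken:
                chosen = c.target_id
                break
        if chosen is None:
            unmapped.add(q)
        else:
            mapping[q] = chosen
            taken.add(chosen)
    if not one_to_one:
        # mapping may be many-to-one; bypass the injectivity check
        hm = HomologyMap.__new__(HomologyMap)
        hm.mapping = mapping
        hm.unmapped = unmapped
        return hm
    return HomologyMap(mapping=mapping, unmapped=unmapped)


def mapping_coverage(hmap: HomologyMap, gene_set: set[str]) -> tuple[int, int]:
    """(number of set members with a resolved target, set size)."""
    n_total = len(gene_set)
    n_mapped = sum(1 for g in gene_set if g in hmap.mapping)
    return n_mapped, n_total
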