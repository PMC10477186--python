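"""Duplicate-genotype detection and distinct-set selection.

Clonally propagated germplasm collections accumulate duplicates: the same
clone deposited under different accession numbers, within or across
genebanks.  A pair is called a duplicate when its individual-level Nei
distance falls at or below 0.025 OR its maximum-likelihood IBD kinship
reaches 0.45 - two calibrations of the same "self" criterion (an AND mode
is available).  Duplicate pairs are merged into clonal groups (connected
components of the duplicate graph) and one representative per group - the
member with the highest call rate, ties broken by lexicographic id - forms
the distinct genotype set together with all unduplicated samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, nei_distance_individuals
from .io_formats import MISSING, GenotypeMatrix, SampleSheet
from .parentage import ml_ibd_pairs

logger = logging.getLogger("dartpop")


@dataclass
class DuplicateCall:
    sample_a: str
    sample_b: str
    nei_distance: float
    ml_kinship: float
    is_duplicate: bool
    same_collection: bool


def find_duplicates(
    gm: GenotypeMatrix,
    sheet: SampleSheet | None = None,
    d_thresh: float = 0.025,
    k_thresh: float = 0.45,
    mode: str = "or",
    nei: DistanceMatrix | None = None,
) -> tuple[list[DuplicateCall], list[list[str]]]:
    """Duplicate calls for every candidate pair plus clonal groups.

    Kinship is evaluated for pairs whose Nei distance is within reach of the
    thresholds (distance <= 4x d_thresh); distant pairs cannot satisfy either
    criterion and are reported with kinship NaN.  ``mode`` combines the two
    criteria with OR (default) or AND.
    """
    for name, v in (("d_thresh", d_thresh), ("k_thresh", k_thresh)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if mode not in ("or", "and"):
        raise ValueError("mode must be 'or' or 'and'")
    dm = nei if nei is not None else nei_distance_individuals(gm)
    ids = dm.ids
    coll = sheet.collection_of() if sheet is not None else {}
    n = len(ids)
    iu = np.triu_indices(n, 1)
    dvals = dm.values[iu]
    screen = dvals <= max(4.0 * d_thresh, 0.1)
    pairs = [(int(a), int(b)) for a, b, s in zip(iu[0], iu[1], screen) if s]
    kin = {}
    if pairs:
        est = ml_ibd_pairs(gm, [(ids[a], ids[b]) for a, b in pairs])
        kin = {p: e for p, e in zip(pairs, est["kinship"].to_numpy())}
    calls: list[DuplicateCall] = []
    edges: list[tuple[int, int]] = []
    for (a, b), d in zip(zip(iu[0], iu[1]), dvals):
        a, b = int(a), int(b)
        phi = kin.get((a, b), np.nan)
        by_d = d <= d_thresh
        by_k = (not np.isnan(phi)) and phi >= k_thresh
        dup = (by_d or by_k) if mode == "or" else (by_d and by_k)
        if dup:
            edges.append((a, b))
        calls.append(
            DuplicateCall(
                ids[a], ids[b], float(d), float(phi), bool(dup),
                coll.get(ids[a]) == coll.get(ids[b]) if coll else True,
            )
        )
    groups = _connected_components(n, edges)
    clonal_groups = [sorted(ids[i] for i in g) for g in groups if len(g) > 1]
    clonal_groups.sort(key=lambda g: g[0])
    logger.info("find_duplicates: %d duplicate pairs, %d clonal groups",
                len(edges), len(clonal_groups))
    return calls, clonal_groups


def _connected_components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def duplicate_count_matrix(
    calls: list[DuplicateCall], sheet: SampleSheet
) -> pd.DataFrame:
    """Collection x collection counts of duplicate pairs (lower triangle +
    diagonal = within-collection)."""
    coll = sheet.collection_of()
    names = sorted(set(coll.values()))
    out = pd.DataFrame(0, index=names, columns=names)
    for c in calls:
        if not c.is_duplicate:
            continue
        a, b = sorted((coll.get(c.sample_a, "?"), coll.get(c.sample_b, "?")))
        if a in names and b in names:
            out.loc[b, a] += 1
    return out


def select_distinct(
    gm: GenotypeMatrix, clonal_groups: list[list[str]]
) -> list[str]:
    """One representative per clonal group (highest call rate, tie ->
    lexicographically smallest id); all ungrouped samples retained.  The
    result has n_samples - sum(group_size - 1) members."""
    obs = gm.calls != MISSING
    call_rate = dict(zip(gm.sample_ids, obs.mean(axis=1)))
    drop: set[str] = set()
    for group in clonal_groups:
        rep = max(group, key=lambda s: (call_rate[s], _neg_lex(s)))
        drop |= set(group) - {rep}
    return [s for s in gm.sample_ids if s not in drop]


class _neg_lex(str):
    """max() with this key prefers the lexicographically smaller string."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)
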