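"""m-of-n consensus voting over replicate call sets.

A variant's detection count m is the number of replicate call sets (of the
same mapper x caller pipeline) containing it; ``consensus(callsets, m)``
returns the keys detected at least m times.  Thresholds are inclusive, so
m=1 is the union and m=n the intersection.  Three grouping schemes mirror
how replicates are pooled in a multi-center study: within_center (one
group per center x pipeline), cross_center (same replicate number across
centers, per pipeline), and all_centers (every replicate of every center,
per pipeline).  Consensus is never taken across different pipelines unless
explicitly overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .variant_io import CallSet, Provenance, VariantKey, sorted_keys

logger = logging.getLogger(__name__)

SCHEME_NAMES = ("within_center", "cross_center", "all_centers")


class ConsensusUsageError(ValueError):
    """Raised for invalid voting requests (mixed pipelines, bad m, ...)."""


def _check_same_pipeline(callsets: Sequence[CallSet], allow_mixed: bool) -> None:
    pipelines = {cs.provenance.pipeline for cs in callsets}
    if len(pipelines) > 1 and not allow_mixed:
        raise ConsensusUsageError(
            f"call sets span {len(pipelines)} pipelines {sorted(pipelines)}; "
            "consensus votes are per-pipeline (pass allow_mixed=True to override)"
        )


def detection_counts(
    callsets: Sequence[CallSet], allow_mixed: bool = False
) -> Mapping[VariantKey, int]:
    """Number of call sets containing each key of the union."""
    if not callsets:
        raise ConsensusUsageError("need at least one call set")
    _check_same_pipeline(callsets, allow_mixed)
    counts: dict = {}
    for cs in callsets:
        for key in cs.keys:
            counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class DetectionMatrix:
    """Candidate keys x call sets boolean incidence table."""

    candidates: List[VariantKey]
    incidence: np.ndarray  # bool, shape (n_candidates, n_callsets)
    sources: List[Provenance]

    @classmethod
    def from_callsets(
        cls, callsets: Sequence[CallSet], allow_mixed: bool = False
    ) -> "DetectionMatrix":
        if not callsets:
            raise ConsensusUsageError("need at least one call set")
        _check_same_pipeline(callsets, allow_mixed)
        candidates = sorted_keys(set().union(*(cs.keys for cs in callsets)))
        incidence = np.zeros((len(candidates), len(callsets)), dtype=bool)
        index = {k: i for i, k in enumerate(candidates)}
        for j, cs in enumerate(callsets):
            for key in cs.keys:
                incidence[index[key], j] = True
        return cls(
            candidates=candidates,
            incidence=incidence,
            sources=[cs.provenance for cs in callsets],
        )

    def counts(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Detection-count table: key fields, count, one 0/1 column per source."""
        cols = {
            "chrom": [k.chrom for k in self.candidates],
            "pos": [k.pos for k in self.candidates],
            "ref": [k.ref for k in self.candidates],
            "alt": [k.alt for k in self.candidates],
            "count": self.counts(),
        }
        for j, prov in enumerate(self.sources):
            label = f"{prov.center}_{prov.replicate}_{prov.mapper}_{prov.caller}"
            cols[label] = self.incidence[:, j].astype(int)
        return pd.DataFrame(cols)


def consensus(
    callsets: Sequence[CallSet],
    m: int,
    allow_mixed: bool = False,
    group_label: str = "",
) -> CallSet:
    """Keys detected in at least ``m`` of the call sets (inclusive).

    Attributes of a consensus key are taken from the first contributing
    call set in list order; provenance records the group label and m.
    """
    if not callsets:
        raise ConsensusUsageError("need at least one call set")
    if not 1 <= m <= len(callsets):
        raise ConsensusUsageError(f"m={m} outside 1..{len(callsets)}")
    counts = detection_counts(callsets, allow_mixed=allow_mixed)
    kept = frozenset(k for k, c in counts.items() if c >= m)
    attrs = {}
    for cs in callsets:  # first-source-wins attribute merge
        for key in cs.keys:
            if key in kept and key not in attrs and key in cs.attrs:
                attrs[key] = cs.attrs[key]
    first = callsets[0].provenance
    prov = Provenance(
        center=group_label or first.center,
        replicate=m,
        mapper=first.mapper,
        caller=first.caller,
    )
    return CallSet(keys=kept, attrs=attrs, provenance=prov)


def pairwise_intersections(
    callsets: Sequence[CallSet], allow_mixed: bool = False
) -> List[Tuple[str, CallSet]]:
    """Intersection of every unordered pair of call sets, C(n,2) results."""
    if len(callsets) < 2:
        raise ConsensusUsageError("pairwise intersections need >= 2 call sets")
    _check_same_pipeline(callsets, allow_mixed)
    out = []
    for (i, a), (j, b) in combinations(enumerate(callsets), 2):
        pa, pb = a.provenance, b.provenance
        label = f"{pa.center}_{pa.replicate}&{pb.center}_{pb.replicate}"
        inter = consensus([a, b], m=2, allow_mixed=allow_mixed, group_label=label)
        out.append((label, inter))
    return out


# ---------------------------------------------------------------------------
# Grouping schemes


@dataclass
class GroupingScheme:
    """Named grouping of manifest rows for consensus voting.

    ``groups`` maps a group label to the list of manifest selectors
    (center, replicate, mapper, caller) voting together.  All selectors in
    one group share a pipeline by construction.
    """

    name: str
    groups: List[Tuple[str, List[Provenance]]] = field(default_factory=list)


REQUIRED_MANIFEST_COLUMNS = ("center", "replicate", "mapper", "caller")


def _validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ConsensusUsageError(f"manifest missing columns: {missing}")
    dup = manifest.duplicated(subset=list(REQUIRED_MANIFEST_COLUMNS))
    if dup.any():
        raise ConsensusUsageError("manifest has duplicate (center, replicate, pipeline) rows")
    return manifest


def build_groups(manifest: pd.DataFrame, scheme: str) -> GroupingScheme:
    """Construct voting groups from a replicate manifest.

    within_center: one group per (center, pipeline) over that center's
    replicates; centers with a single replicate are excluded with a logged
    notice.  cross_center: one group per (replicate number, pipeline)
    spanning centers; replicate numbers present in fewer than two centers
    are excluded.  all_centers: one group per pipeline over every center x
    replicate.
    """
    if scheme not in SCHEME_NAMES:
        raise ConsensusUsageError(f"unknown scheme {scheme!r}; one of {SCHEME_NAMES}")
    manifest = _validate_manifest(manifest)
    rows = [
        Provenance(str(r.center), int(r.replicate), str(r.mapper), str(r.caller))
        for r in manifest.itertuples()
    ]
    pipelines = sorted({p.pipeline for p in rows})
    groups: list = []

    if scheme == "within_center":
        centers = sorted({p.center for p in rows})
        for center in centers:
            center_rows = [p for p in rows if p.center == center]
            n_reps = len({p.replicate for p in center_rows})
            if n_reps < 2:
                logger.info(
                    "within_center: excluding center %s with %d replicate(s)",
                    center, n_reps,
                )
                continue
            for mapper, caller in pipelines:
                members = sorted(
                    p for p in center_rows if p.pipeline == (mapper, caller)
                )
                if members:
                    groups.append((f"{center}_{mapper}_{caller}", members))
    elif scheme == "cross_center":
        rep_numbers = sorted({p.replicate for p in rows})
        for rep in rep_numbers:
            rep_rows = [p for p in rows if p.replicate == rep]
            n_centers = len({p.center for p in rep_rows})
            if n_centers < 2:
                logger.info(
                    "cross_center: excluding replicate %s spanning %d center(s)",
                    rep, n_centers,
                )
                continue
            for mapper, caller in pipelines:
                members = sorted(p for p in rep_rows if p.pipeline == (mapper, caller))
                if members:
                    groups.append((f"rep{rep}_{mapper}_{caller}", members))
    else:  # all_centers
        for mapper, caller in pipelines:
            members = sorted(p for p in rows if p.pipeline == (mapper, caller))
            if members:
                groups.append((f"all_{mapper}_{caller}", members))

    if not groups:
        logger.warning("scheme %s produced no voting groups from this manifest", scheme)
    return GroupingScheme(name=scheme, groups=groups)
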