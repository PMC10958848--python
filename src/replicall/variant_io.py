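"""VCF/BED input-output and variant set algebra primitives.

All downstream consensus and benchmarking operations work on sets of
:class:`VariantKey` — the (chrom, pos, ref, alt) identity of a called
variant.  VCF positions are 1-based; BED intervals are 0-based half-open,
so region membership tests use ``pos - 1``.

Indel left-alignment / normalization is not performed: the pipeline is
SNV-oriented and callers' SNV records are already atomic after
multi-allelic splitting.  Apply :func:`select_snvs` before comparing call
sets that may contain indels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional

from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class VariantIOError(ValueError):
    """Raised for unreadable or malformed VCF/BED input."""


class VariantKey(NamedTuple):
    """Identity of a called variant used for all set algebra.

    Two keys are equal iff chromosome, 1-based position, reference allele
    and alternate allele are all equal after normalization (uppercase
    alleles, optional chr-prefix handling at read time).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def validate(self) -> "VariantKey":
        if self.pos < 1:
            raise VariantIOError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantIOError("ref and alt must be non-empty")
        if set(self.ref) - _VALID_BASES or set(self.alt) - _VALID_BASES:
            raise VariantIOError(f"alleles must be over ACGTN: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise VariantIOError(f"ref == alt at {self.chrom}:{self.pos}")
        return self


class CallAttributes(NamedTuple):
    """Per-call numeric attributes carried alongside a key.

    These feed the classifier as features; any field may be absent (None).
    """

    qual: Optional[float] = None
    filter: str = "PASS"
    vaf: Optional[float] = None
    tumor_depth: Optional[int] = None
    normal_depth: Optional[int] = None

    def validate(self) -> "CallAttributes":
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise VariantIOError(f"VAF out of [0,1]: {self.vaf}")
        for d in (self.tumor_depth, self.normal_depth):
            if d is not None and d < 0:
                raise VariantIOError(f"negative depth: {d}")
        return self


class Provenance(NamedTuple):
    """Where a call set came from: sequencing center, biological replicate
    number, and the mapper x caller pipeline that produced it."""

    center: str = ""
    replicate: int = 0
    mapper: str = ""
    caller: str = ""

    @property
    def pipeline(self) -> tuple:
        return (self.mapper, self.caller)


@dataclass
class CallSet:
    """One replicate x pipeline's deduplicated set of variant keys."""

    keys: frozenset
    attrs: Mapping[VariantKey, CallAttributes] = field(default_factory=dict)
    provenance: Provenance = Provenance()

    def __post_init__(self):
        self.keys = frozenset(self.keys)
        extra = set(self.attrs) - self.keys
        if extra:
            raise VariantIOError(f"{len(extra)} attribute keys missing from key set")

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys

    def __iter__(self):
        return iter(self.keys)

    def with_keys(self, keys: Iterable[VariantKey]) -> "CallSet":
        """A new call set holding ``keys``, keeping matching attributes
        and the same provenance."""
        keys = frozenset(keys)
        attrs = {k: v for k, v in self.attrs.items() if k in keys}
        return CallSet(keys=keys, attrs=attrs, provenance=self.provenance)


def _normalize_chrom(chrom: str, chr_prefix: str) -> str:
    if chr_prefix == "add":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if chr_prefix == "strip":
        return chrom[3:] if chrom.startswith("chr") else chrom
    return chrom


def chrom_sort_key(chrom: str) -> tuple:
    """Karyotype-aware sort: chr2 before chr10, numbered before X/Y/M."""
    c = chrom[3:] if chrom.startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


@dataclass
class RegionSet:
    """Merged genomic intervals in BED convention (0-based, half-open).

    Overlapping or adjacent intervals on one chromosome are merged on
    construction, so the internal trees hold disjoint intervals.
    """

    trees: Mapping[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple]) -> "RegionSet":
        trees: dict = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if not 0 <= start < end:
                raise VariantIOError(f"bad interval {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in trees.values():
            tree.merge_overlaps(strict=False)  # merge touching intervals too
        return cls(trees=trees)

    def intervals(self) -> list:
        """Sorted (chrom, start, end) triples."""
        out = []
        for chrom in sorted(self.trees, key=chrom_sort_key):
            for iv in sorted(self.trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based VCF position."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree[pos - 1])

    def total_length(self) -> int:
        return sum(iv.end - iv.begin for t in self.trees.values() for iv in t)

    @property
    def chroms(self) -> list:
        return sorted(self.trees, key=chrom_sort_key)

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def _attrs_from_record(variant, filter_label: str) -> CallAttributes:
    qual = None if variant.QUAL is None else float(variant.QUAL)
    info = dict(variant.INFO)
    vaf = info.get("VAF", info.get("AF"))
    if isinstance(vaf, (tuple, list)):
        vaf = vaf[0] if vaf else None
    tdp = info.get("TDP")
    ndp = info.get("NDP")
    return CallAttributes(
        qual=qual,
        filter=filter_label,
        vaf=None if vaf is None else float(vaf),
        tumor_depth=None if tdp is None else int(tdp),
        normal_depth=None if ndp is None else int(ndp),
    ).validate()


def read_vcf(
    path,
    pass_only: bool = False,
    provenance: Provenance = Provenance(),
    chr_prefix: str = "keep",
) -> CallSet:
    """Read a VCF 4.x file (plain or bgzipped) into a :class:`CallSet`.

    One key is produced per (record, alt allele); multi-allelic records are
    split.  With ``pass_only`` records whose FILTER is neither PASS nor "."
    are dropped — "." counts as passing because unfiltered caller output
    (e.g. SomaticSniper) carries no PASS label.  Duplicate keys collapse to
    one, keeping the first record's attributes.  ``provenance`` is supplied
    by the caller, not parsed from the file.

    ``chr_prefix``: "keep" (default), "add", or "strip" normalizes
    chromosome labels across VCF dialects.
    """
    path = Path(path)
    if not path.exists():
        raise VariantIOError(f"VCF not found: {path}")
    try:
        reader = VCF(str(path))
    except Exception as exc:  # htslib open failure
        raise VariantIOError(f"cannot read VCF {path}: {exc}") from exc

    keys: list = []
    attrs: dict = {}
    n_record = 0
    try:
        for variant in reader:
            n_record += 1
            # cyvcf2 reports FILTER as None for both PASS and "."
            filter_label = variant.FILTER if variant.FILTER else "PASS"
            if pass_only and filter_label != "PASS":
                continue
            chrom = _normalize_chrom(str(variant.CHROM), chr_prefix)
            ref = str(variant.REF).upper()
            for alt in variant.ALT:
                alt = str(alt).upper()
                if alt in ("<NON_REF>", "*", "."):
                    continue
                key = VariantKey(chrom, int(variant.POS), ref, alt).validate()
                if key not in attrs:
                    keys.append(key)
                    attrs[key] = _attrs_from_record(variant, filter_label)
    except VariantIOError as exc:
        raise VariantIOError(f"{path} record {n_record}: {exc}") from exc
    except Exception as exc:
        raise VariantIOError(f"{path}: malformed record {n_record}: {exc}") from exc
    finally:
        reader.close()
    return CallSet(keys=frozenset(keys), attrs=attrs, provenance=provenance)


def read_bed(path, chr_prefix: str = "keep") -> RegionSet:
    """Read a 3+ column BED file into a merged :class:`RegionSet`.

    Extra columns are ignored; header/comment lines (track, browser, #)
    are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise VariantIOError(f"BED not found: {path}")
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise VariantIOError(f"{path} line {lineno}: fewer than 3 columns")
            chrom = _normalize_chrom(fields[0], chr_prefix)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise VariantIOError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise VariantIOError(
                    f"{path} line {lineno}: start >= end ({start} >= {end})"
                )
            if start < 0:
                raise VariantIOError(f"{path} line {lineno}: negative start")
            intervals.append((chrom, start, end))
    return RegionSet.from_intervals(intervals)


def restrict(cs: CallSet, regions: RegionSet) -> CallSet:
    """Keep exactly the keys whose position falls inside ``regions``."""
    kept = frozenset(k for k in cs.keys if regions.contains(k.chrom, k.pos))
    if cs.keys and regions.trees and not kept:
        shared = set(k.chrom for k in cs.keys) & set(regions.trees)
        if not shared:
            warnings.warn(
                "restrict: call set and regions share no chromosome labels; "
                "check chr-prefix conventions",
                stacklevel=2,
            )
    return cs.with_keys(kept)


def select_snvs(cs: CallSet) -> CallSet:
    """Keep single-nucleotide substitutions (len(ref) == len(alt) == 1)."""
    return cs.with_keys(k for k in cs.keys if k.is_snv)


def sorted_keys(keys: Iterable[VariantKey]) -> list:
    return sorted(keys, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.ref, k.alt))


def write_vcf(cs: CallSet, path, extra_header_lines: Iterable[str] = ()) -> None:
    """Write a minimal sorted VCF 4.2; round-trips through :func:`read_vcf`.

    QUAL and the VAF/TDP/NDP INFO fields are emitted when present so
    attributes survive a round trip too.
    """
    path = Path(path)
    keys = sorted_keys(cs.keys)
    filters = sorted(
        {a.filter for a in cs.attrs.values() if a.filter not in ("PASS", ".")}
    )
    chroms = sorted({k.chrom for k in keys}, key=chrom_sort_key)
    lines = ["##fileformat=VCFv4.2"]
    lines += list(extra_header_lines)
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
        '##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumor read depth">',
        '##INFO=<ID=NDP,Number=1,Type=Integer,Description="Normal read depth">',
    ]
    lines += [f'##FILTER=<ID={f},Description="{f}">' for f in filters]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for key in keys:
        a = cs.attrs.get(key, CallAttributes())
        qual = "." if a.qual is None else f"{a.qual:g}"
        info_parts = []
        if a.vaf is not None:
            info_parts.append(f"VAF={a.vaf:.6g}")
        if a.tumor_depth is not None:
            info_parts.append(f"TDP={a.tumor_depth}")
        if a.normal_depth is not None:
            info_parts.append(f"NDP={a.normal_depth}")
        info = ";".join(info_parts) or "."
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t{qual}\t{a.filter}\t{info}"
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise VariantIOError(f"cannot write VCF {path}: {exc}") from exc


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as a 3-column BED."""
    lines = [f"{c}\t{s}\t{e}" for c, s, e in regions.intervals()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
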