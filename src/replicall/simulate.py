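"""Synthetic multi-center replicate studies of somatic SNV calling.

Generates a complete study — truth SNVs with a VAF spectrum, an exome-like
target BED, a replicate manifest, and one call set per center x replicate
x (mapper, caller) pipeline — with an error structure built from two
mechanisms:

* **Sensitivity** is logistic in VAF x sequencing depth: a truth variant is
  detected with probability ``sigmoid(slope * VAF * depth + intercept)``,
  with per-site depth drawn Poisson around the replicate's mean coverage.
  Higher-coverage centers therefore recall more low-VAF variants.
* **False positives** come from three pools: center-shared artifact sites
  (recurring across one center's replicates and pipelines, emulating
  library-prep/batch artifacts), caller-shared systematic sites (recurring
  wherever one caller runs), and private Poisson noise unique to a call
  set.  Shared-pool sites enter each call set with a per-site inclusion
  probability, which is what makes m-of-n voting behave differently under
  within-center versus cross-center grouping.

Randomness is organised as one independent stream per (center, replicate,
pipeline) spawned from the master seed, so adding a pipeline or replicate
never perturbs previously generated call sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variant_io import (
    CallAttributes,
    CallSet,
    Provenance,
    RegionSet,
    VariantKey,
    read_bed,
    read_vcf,
    write_bed,
    write_vcf,
)

_BASES = np.array(list("ACGT"))

# sub-stream tags under the master seed
_TAG_TRUTH, _TAG_POOLS, _TAG_CALLS = 1, 2, 3


class StudyConfigError(ValueError):
    pass


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class VAFMixture:
    """Truth VAF spectrum: clonal Gaussian peaks plus a subclonal Beta tail.

    ``peaks`` are (mean, sd, weight) triples; ``tail`` is (alpha, beta,
    weight).  Weights must sum to 1; draws are clipped to [vmin, vmax].
    """

    peaks: Tuple[Tuple[float, float, float], ...] = (
        (0.50, 0.05, 0.45),  # clonal heterozygous-like peak
        (0.25, 0.04, 0.25),  # subclonal major clone
    )
    tail: Tuple[float, float, float] = (2.0, 8.0, 0.30)
    vmin: float = 0.02
    vmax: float = 0.98

    def __post_init__(self):
        w = sum(p[2] for p in self.peaks) + self.tail[2]
        if abs(w - 1.0) > 1e-9:
            raise StudyConfigError(f"VAF mixture weights sum to {w}, not 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = [p[2] for p in self.peaks] + [self.tail[2]]
        which = rng.choice(len(weights), size=n, p=weights)
        out = np.empty(n)
        for i, (mu, sd, _) in enumerate(self.peaks):
            mask = which == i
            out[mask] = rng.normal(mu, sd, mask.sum())
        mask = which == len(self.peaks)
        a, b, _ = self.tail
        out[mask] = rng.beta(a, b, mask.sum())
        return np.clip(out, self.vmin, self.vmax)


@dataclass(frozen=True)
class CallerModel:
    """Per-caller sensitivity and error parameters.

    Detection probability of a truth variant is
    ``sigmoid(slope * VAF * depth + intercept)``; ``slope=0`` gives a
    constant, coverage-independent sensitivity of ``sigmoid(intercept)``.
    """

    slope: float = 0.15
    intercept: float = -0.4
    private_fp_rate: float = 250.0  # Poisson mean of unique FP sites per call set
    shared_artifact_sites: int = 60  # caller-systematic pool size, study-wide
    qual_mean: float = 35.0  # mean reported QUAL for true calls
    qual_mean_fp: float = 18.0

    @classmethod
    def constant(cls, sensitivity: float, **kw) -> "CallerModel":
        """Coverage-independent sensitivity (exact, for calibration runs)."""
        return cls(slope=0.0, intercept=_logit(sensitivity), **kw)

    @classmethod
    def perfect(cls) -> "CallerModel":
        """Sensitivity 1, no false positives (the noiseless limit)."""
        return cls(slope=0.0, intercept=40.0, private_fp_rate=0.0,
                   shared_artifact_sites=0)


@dataclass(frozen=True)
class CenterProfile:
    """A sequencing center: per-replicate mean coverages and its shared
    artifact pool size."""

    name: str
    coverage_means: Tuple[float, ...] = (100.0, 100.0, 100.0)
    center_artifact_sites: int = 80

    @property
    def n_replicates(self) -> int:
        return len(self.coverage_means)


def _default_centers() -> Tuple[CenterProfile, ...]:
    # Analogues of the three triple-replicate centers: one low-coverage
    # center and two higher-coverage ones (one with an outlier deep replicate).
    return (
        CenterProfile("FD", (55.0, 60.0, 65.0)),
        CenterProfile("IL", (95.0, 240.0, 110.0)),
        CenterProfile("NV", (100.0, 105.0, 95.0)),
    )


def _default_callers() -> Dict[str, CallerModel]:
    return {
        "mutect": CallerModel(slope=0.18, intercept=-0.3, private_fp_rate=150.0,
                              shared_artifact_sites=25, qual_mean=40.0),
        "strelka": CallerModel(slope=0.15, intercept=-0.4, private_fp_rate=250.0,
                               shared_artifact_sites=60, qual_mean=32.0),
        "ss": CallerModel(slope=0.12, intercept=-0.5, private_fp_rate=450.0,
                          shared_artifact_sites=140, qual_mean=25.0),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Full specification of a simulated study.

    Defaults mirror the benchmark setting: a truth set of 1,159 somatic
    SNVs inside exome-like targets, three triple-replicate centers, two
    mappers and three callers (six pipelines).
    """

    n_truth: int = 1159
    chroms: Tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 11))
    targets_per_chrom: int = 120
    target_length: int = 1000
    target_spacing: int = 8000
    vaf_mixture: VAFMixture = field(default_factory=VAFMixture)
    centers: Tuple[CenterProfile, ...] = field(default_factory=_default_centers)
    mappers: Mapping[str, float] = field(  # name -> effective-depth multiplier
        default_factory=lambda: {"bwa": 1.0, "bowtie": 0.92}
    )
    callers: Mapping[str, CallerModel] = field(default_factory=_default_callers)
    pool_inclusion_prob: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_truth < 1:
            raise StudyConfigError("n_truth must be >= 1")
        if not (0.0 <= self.pool_inclusion_prob <= 1.0):
            raise StudyConfigError("pool_inclusion_prob must be in [0,1]")
        if self.target_length < 1 or self.targets_per_chrom < 1:
            raise StudyConfigError("targets must be non-empty")
        if self.target_spacing < self.target_length:
            raise StudyConfigError("target_spacing must be >= target_length")

    @property
    def pipelines(self) -> List[Tuple[str, str]]:
        return [(m, c) for m in self.mappers for c in self.callers]

    @property
    def bases_per_chrom(self) -> int:
        return self.targets_per_chrom * self.target_length

    @property
    def covered_bases(self) -> int:
        return len(self.chroms) * self.bases_per_chrom

    def offset_to_site(self, offset: int) -> Tuple[str, int]:
        """Map a covered-base index to (chrom, 1-based position)."""
        chrom_idx, within = divmod(int(offset), self.bases_per_chrom)
        target_idx, off = divmod(within, self.target_length)
        return self.chroms[chrom_idx], target_idx * self.target_spacing + off + 1

    def regions(self) -> RegionSet:
        intervals = [
            (chrom, t * self.target_spacing, t * self.target_spacing + self.target_length)
            for chrom in self.chroms
            for t in range(self.targets_per_chrom)
        ]
        return RegionSet.from_intervals(intervals)

    def replace(self, **kw) -> "StudyConfig":
        return dataclasses.replace(self, **kw)


def config_to_dict(cfg: StudyConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: Mapping) -> StudyConfig:
    d = dict(d)
    if "vaf_mixture" in d and not isinstance(d["vaf_mixture"], VAFMixture):
        vm = dict(d["vaf_mixture"])
        vm["peaks"] = tuple(tuple(p) for p in vm.get("peaks", ()))
        vm["tail"] = tuple(vm["tail"])
        d["vaf_mixture"] = VAFMixture(**vm)
    if "centers" in d:
        centers = []
        for c in d["centers"]:
            if not isinstance(c, CenterProfile):
                c = dict(c)
                c["coverage_means"] = tuple(c["coverage_means"])
                c = CenterProfile(**c)
            centers.append(c)
        d["centers"] = tuple(centers)
    if "callers" in d:
        d["callers"] = {
            name: cm if isinstance(cm, CallerModel) else CallerModel(**cm)
            for name, cm in d["callers"].items()
        }
    if "chroms" in d:
        d["chroms"] = tuple(d["chroms"])
    return StudyConfig(**d)


def config_hash(cfg: StudyConfig) -> str:
    """Stable sha256 over the canonical JSON form of the config."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Site machinery


@dataclass(frozen=True)
class _Site:
    key: VariantKey
    vaf: float  # true VAF for truth sites; typical artifact VAF for FP sites


def _draw_sites(
    cfg: StudyConfig,
    rng: np.random.Generator,
    n: int,
    vafs: np.ndarray,
    exclude: frozenset,
) -> List[_Site]:
    """Draw n unique sites (unique offsets) avoiding ``exclude`` keys."""
    sites: List[_Site] = []
    seen = set()
    while len(sites) < n:
        need = n - len(sites)
        offsets = rng.integers(0, cfg.covered_bases, size=max(need * 2, 16))
        refs = rng.integers(0, 4, size=offsets.size)
        alt_shift = rng.integers(1, 4, size=offsets.size)
        for i in range(offsets.size):
            if len(sites) >= n:
                break
            off = int(offsets[i])
            if off in seen:
                continue
            chrom, pos = cfg.offset_to_site(off)
            ref = _BASES[refs[i]]
            alt = _BASES[(refs[i] + alt_shift[i]) % 4]
            key = VariantKey(chrom, pos, str(ref), str(alt))
            if key in exclude:
                continue
            seen.add(off)
            sites.append(_Site(key=key, vaf=float(vafs[len(sites)])))
    return sites


def simulate_truth(cfg: StudyConfig) -> Tuple[CallSet, RegionSet]:
    """Truth SNVs at unique in-region positions with mixture-drawn VAFs."""
    if cfg.n_truth > cfg.covered_bases:
        raise StudyConfigError(
            f"regions cover {cfg.covered_bases} bases < n_truth={cfg.n_truth}"
        )
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, _TAG_TRUTH)))
    vafs = cfg.vaf_mixture.sample(rng, cfg.n_truth)
    sites = _draw_sites(cfg, rng, cfg.n_truth, vafs, frozenset())
    attrs = {s.key: CallAttributes(vaf=s.vaf) for s in sites}
    truth = CallSet(
        keys=frozenset(attrs),
        attrs=attrs,
        provenance=Provenance(center="truth"),
    )
    return truth, cfg.regions()


@dataclass(frozen=True)
class SharedPools:
    """Study-wide artifact pools, generated once per study."""

    center_pools: Mapping[str, Tuple[_Site, ...]]  # center name -> sites
    caller_pools: Mapping[str, Tuple[_Site, ...]]  # caller name -> sites


def _make_pools(cfg: StudyConfig, truth_keys: frozenset) -> SharedPools:
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, _TAG_POOLS)))
    exclude = set(truth_keys)
    center_pools = {}
    for profile in cfg.centers:
        n = profile.center_artifact_sites
        vafs = rng.beta(1.5, 12.0, size=n)
        sites = _draw_sites(cfg, rng, n, vafs, frozenset(exclude))
        exclude.update(s.key for s in sites)
        center_pools[profile.name] = tuple(sites)
    caller_pools = {}
    for caller, model in cfg.callers.items():
        n = model.shared_artifact_sites
        vafs = rng.beta(1.5, 12.0, size=n)
        sites = _draw_sites(cfg, rng, n, vafs, frozenset(exclude))
        exclude.update(s.key for s in sites)
        caller_pools[caller] = tuple(sites)
    return SharedPools(center_pools=center_pools, caller_pools=caller_pools)


def _fp_attributes(
    rng: np.random.Generator, n: int, coverage: float, qual_mean: float
) -> List[CallAttributes]:
    depths = np.maximum(1, rng.poisson(coverage, size=n))
    ndepths = rng.poisson(coverage, size=n)
    vafs = rng.beta(1.5, 12.0, size=n)
    quals = np.maximum(0.0, rng.normal(qual_mean, 6.0, size=n))
    return [
        CallAttributes(
            qual=float(quals[i]),
            vaf=float(min(vafs[i], 1.0)),
            tumor_depth=int(depths[i]),
            normal_depth=int(ndepths[i]),
        )
        for i in range(n)
    ]


def simulate_replicate(
    truth: CallSet,
    profile: CenterProfile,
    replicate_index: int,
    pipeline: Tuple[str, str],
    pools: SharedPools,
    rng: np.random.Generator,
    cfg: StudyConfig,
) -> CallSet:
    """One call set: logistic VAF x depth detection of truth variants plus
    pool-shared and private false positives.

    ``replicate_index`` is 0-based; the emitted provenance uses 1-based
    replicate numbers.
    """
    mapper, caller = pipeline
    model = cfg.callers[caller]
    coverage = profile.coverage_means[replicate_index] * cfg.mappers[mapper]

    truth_sites = sorted(truth.keys)
    true_vafs = np.array([truth.attrs[k].vaf for k in truth_sites])
    n = len(truth_sites)
    depths = np.maximum(1, rng.poisson(coverage, size=n))
    p_detect = _expit(model.slope * true_vafs * depths + model.intercept)
    detected = rng.random(n) < p_detect

    alt_reads = np.maximum(1, rng.binomial(depths, true_vafs))
    obs_vaf = np.minimum(alt_reads / depths, 1.0)
    normal_depths = rng.poisson(coverage, size=n)
    quals = np.maximum(0.0, rng.normal(model.qual_mean, 8.0, size=n))

    attrs: Dict[VariantKey, CallAttributes] = {}
    for i in np.flatnonzero(detected):
        key = truth_sites[i]
        attrs[key] = CallAttributes(
            qual=float(quals[i]),
            vaf=float(obs_vaf[i]),
            tumor_depth=int(depths[i]),
            normal_depth=int(normal_depths[i]),
        )

    # shared artifact pools: per-site Bernoulli inclusion per call set
    for pool in (pools.center_pools.get(profile.name, ()),
                 pools.caller_pools.get(caller, ())):
        if not pool:
            continue
        included = rng.random(len(pool)) < cfg.pool_inclusion_prob
        idx = np.flatnonzero(included)
        fp_attrs = _fp_attributes(rng, idx.size, coverage, model.qual_mean_fp)
        for j, i in enumerate(idx):
            site = pool[i]
            if site.key not in attrs:
                attrs[site.key] = fp_attrs[j]

    # private false positives, fresh each call set
    n_private = int(rng.poisson(model.private_fp_rate))
    if n_private:
        vafs = rng.beta(1.5, 12.0, size=n_private)
        exclude = frozenset(truth.keys) | {s.key for p in (pools.center_pools, pools.caller_pools) for ss in p.values() for s in ss}
        sites = _draw_sites(cfg, rng, n_private, vafs, exclude)
        fp_attrs = _fp_attributes(rng, n_private, coverage, model.qual_mean_fp)
        for site, a in zip(sites, fp_attrs):
            if site.key not in attrs:
                attrs[site.key] = a

    prov = Provenance(
        center=profile.name,
        replicate=replicate_index + 1,
        mapper=mapper,
        caller=caller,
    )
    return CallSet(keys=frozenset(attrs), attrs=attrs, provenance=prov)


@dataclass
class StudyBundle:
    """A simulated study: truth, regions, manifest and all call sets."""

    truth: CallSet
    regions: RegionSet
    manifest: pd.DataFrame
    callsets: Dict[Tuple[str, int, str, str], CallSet]  # (center, rep, mapper, caller)
    config: StudyConfig

    def callsets_for(self, members: Sequence[Provenance]) -> List[CallSet]:
        return [
            self.callsets[(p.center, p.replicate, p.mapper, p.caller)]
            for p in members
        ]

    def materialize(self, outdir, extra_header_lines: Sequence[str] = ()) -> Path:
        """Write truth VCF, region BED, manifest TSV and per-call-set VCFs."""
        outdir = Path(outdir)
        calls_dir = outdir / "calls"
        calls_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.truth, outdir / "truth.vcf",
                  extra_header_lines=extra_header_lines)
        write_bed(self.regions, outdir / "regions.bed")
        manifest = self.manifest.copy()
        paths = []
        for row in manifest.itertuples():
            name = f"{row.center}_{row.replicate}_{row.mapper}_{row.caller}.vcf"
            cs = self.callsets[(row.center, row.replicate, row.mapper, row.caller)]
            write_vcf(cs, calls_dir / name, extra_header_lines=extra_header_lines)
            paths.append(str(Path("calls") / name))
        manifest["vcf_path"] = paths
        manifest["pass_only"] = False
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        payload = {"config": config_to_dict(self.config),
                   "config_hash": config_hash(self.config)}
        (outdir / "config.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=list) + "\n"
        )
        return outdir


def simulate_study(cfg: StudyConfig) -> StudyBundle:
    """Generate the full bundle: one call set per center x replicate x
    pipeline, deterministic given ``cfg.seed``."""
    truth, regions = simulate_truth(cfg)
    pools = _make_pools(cfg, truth.keys)
    callsets: Dict[Tuple[str, int, str, str], CallSet] = {}
    rows = []
    for ci, profile in enumerate(cfg.centers):
        for ri in range(profile.n_replicates):
            for pi, pipeline in enumerate(cfg.pipelines):
                rng = np.random.default_rng(
                    np.random.SeedSequence((cfg.seed, _TAG_CALLS, ci, ri, pi))
                )
                cs = simulate_replicate(truth, profile, ri, pipeline, pools, rng, cfg)
                mapper, caller = pipeline
                callsets[(profile.name, ri + 1, mapper, caller)] = cs
                rows.append(
                    {"center": profile.name, "replicate": ri + 1,
                     "mapper": mapper, "caller": caller}
                )
    manifest = pd.DataFrame(rows)
    return StudyBundle(truth=truth, regions=regions, manifest=manifest,
                       callsets=callsets, config=cfg)


def load_bundle(path, cfg: Optional[StudyConfig] = None) -> StudyBundle:
    """Read a materialized bundle back from disk."""
    path = Path(path)
    if cfg is None and (path / "config.json").exists():
        payload = json.loads((path / "config.json").read_text())
        cfg = config_from_dict(payload["config"])
    truth = read_vcf(path / "truth.vcf", provenance=Provenance(center="truth"))
    regions = read_bed(path / "regions.bed")
    manifest = pd.read_csv(path / "manifest.tsv", sep="\t", comment="#")
    callsets = {}
    for row in manifest.itertuples():
        prov = Provenance(str(row.center), int(row.replicate),
                          str(row.mapper), str(row.caller))
        cs = read_vcf(path / row.vcf_path, pass_only=bool(row.pass_only),
                      provenance=prov)
        callsets[(prov.center, prov.replicate, prov.mapper, prov.caller)] = cs
    return StudyBundle(
        truth=truth, regions=regions,
        manifest=manifest[["center", "replicate", "mapper", "caller"]].copy(),
        callsets=callsets, config=cfg if cfg is not None else StudyConfig(),
    )


def estimate_profile(bundle: StudyBundle) -> pd.DataFrame:
    """Empirical per-call-set sensitivity and false-positive counts.

    sensitivity = fraction of truth keys present in the call set;
    fp_count = number of called keys outside the truth set.  Aggregate by
    caller to recover configured parameters in calibration runs.
    """
    truth_keys = bundle.truth.keys
    n_truth = len(truth_keys)
    rows = []
    for (center, rep, mapper, caller), cs in sorted(bundle.callsets.items()):
        tp = len(cs.keys & truth_keys)
        rows.append(
            {
                "center": center, "replicate": rep,
                "mapper": mapper, "caller": caller,
                "sensitivity": tp / n_truth if n_truth else 0.0,
                "fp_count": len(cs.keys) - tp,
            }
        )
    return pd.DataFrame(rows)
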