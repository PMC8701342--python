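"""Synthetic data with planted, recorded truth.

Every downstream stage (plasmid copy number, disomy/segment calling,
variant recurrence, ΔΔCT quantification, concordance) is testable against
the truth records these generators emit — no external download needed.

Depth noise is negative-binomial per bin: for size parameter (dispersion)
``r`` and mean ``m``, variance is ``m + m**2 / r``.  A deterministic mode
(noise disabled) returns expected values exactly for identity tests.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .coverage import BinnedTrack, DepthTrack
from .qpcr import QpcrMeasurement
from .regions import RegionMask
from .variants import VariantRecord

# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeLayout:
    """Named sequences with lengths, plus intervals excluded from the
    genome-mean computation (e.g. a mitochondrial-like contig)."""

    sequences: List[Tuple[str, int]]
    excluded: RegionMask = field(default_factory=RegionMask)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise ValueError("sequence names must be unique")
        for name, length in self.sequences:
            if length < 1:
                raise ValueError(f"sequence {name!r} has non-positive length")
        self.excluded.validate_within(self.lengths)

    @property
    def lengths(self) -> Dict[str, int]:
        return dict(self.sequences)


@dataclass
class EventSet:
    """Planted copy-number events.

    ``disomies`` lists whole chromosomes at ploidy factor 2; ``segments``
    are (sequence, start, end, factor) local duplications.  Overlapping
    events multiply.
    """

    plasmid_cn: float = 0.0
    disomies: frozenset = frozenset()
    segments: List[Tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plasmid_cn < 0:
            raise ValueError("plasmid_cn must be non-negative")
        self.disomies = frozenset(self.disomies)
        for seq, start, end, factor in self.segments:
            if factor <= 0:
                raise ValueError(f"segment factor must be > 0, got {factor}")
            if end <= start:
                raise ValueError(f"empty segment ({start}, {end}) on {seq}")

    def factor_profile(self, sequence: str, length: int) -> np.ndarray:
        """Per-base ploidy factor along ``sequence``."""
        prof = np.ones(length)
        if sequence in self.disomies:
            prof *= 2.0
        for seq, start, end, factor in self.segments:
            if seq == sequence:
                if start < 0 or end > length:
                    raise ValueError(
                        f"segment ({start}, {end}) outside {sequence} of length {length}"
                    )
                prof[start:end] *= factor
        return prof

    def to_truth(self) -> dict:
        return {
            "plasmid_cn": self.plasmid_cn,
            "disomies": sorted(self.disomies),
            "segments": [list(s) for s in self.segments],
        }


@dataclass
class NoiseModel:
    """Negative-binomial depth noise; identical seed+parameters reproduce
    identical output."""

    mean_depth: float = 30.0
    dispersion: float = 10.0
    seed: int = 0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def nb_draw(
    rng: np.random.Generator,
    mean: np.ndarray,
    dispersion: float,
    deterministic: bool = False,
) -> np.ndarray:
    """Negative-binomial draws with the given per-element means."""
    mean = np.asarray(mean, dtype=float)
    if deterministic:
        return mean.copy()
    out = np.zeros_like(mean)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


# ---------------------------------------------------------------------------
# depth simulation


def simulate_depth(
    layout: GenomeLayout,
    events: EventSet,
    noise: NoiseModel,
    bin_size: int = 1000,
) -> Tuple[Dict[str, BinnedTrack], dict]:
    """Simulate binned genome coverage with planted events.

    Each bin's depth is drawn from a negative binomial whose mean is
    ``mean_depth`` times the bin's mean local ploidy factor (factors of
    overlapping events multiply).  Returns the tracks and a truth record.
    """
    min_len = min(length for _, length in layout.sequences)
    if bin_size > min_len:
        raise ValueError(f"bin_size {bin_size} exceeds shortest sequence ({min_len})")
    rng = noise.rng()
    tracks: Dict[str, BinnedTrack] = {}
    for name, length in layout.sequences:
        n_bins = -(-length // bin_size)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        has_event = name in events.disomies or any(
            s[0] == name for s in events.segments
        )
        if has_event:
            prof = events.factor_profile(name, length)
            # mean factor per bin (exact also for partial trailing bin)
            csum = np.concatenate([[0.0], np.cumsum(prof)])
            bin_factor = (csum[ends] - csum[starts]) / (ends - starts)
        else:
            bin_factor = np.ones(n_bins)
        means = nb_draw(
            rng, noise.mean_depth * bin_factor, noise.dispersion, noise.deterministic
        )
        tracks[name] = BinnedTrack(name, starts, ends, means, bin_size)
    truth = {
        "events": events.to_truth(),
        "mean_depth": noise.mean_depth,
        "dispersion": noise.dispersion,
        "seed": noise.seed,
        "deterministic": noise.deterministic,
        "bin_size": bin_size,
        "sequences": [list(s) for s in layout.sequences],
    }
    return tracks, truth


def simulate_plasmid_depth(
    spec,
    plasmid_cn: float,
    genome_mean: float,
    noise: NoiseModel,
    bin_size: int = 100,
) -> DepthTrack:
    """Simulate per-base plasmid depth for a planted copy number.

    Expected depth is ``genome_mean * plasmid_cn`` on plasmid-specific bases
    and ``genome_mean * (plasmid_cn + 1)`` on bases shared with the genome
    (the single genomic locus also contributes reads there).  Noise is drawn
    per bin and expanded to bases; deterministic mode returns expectations
    exactly.
    """
    if plasmid_cn < 0:
        raise ValueError("plasmid_cn must be non-negative")
    if genome_mean <= 0:
        raise ValueError("genome_mean must be > 0")
    length = spec.length
    shared = spec.shared.membership(spec.name, length)
    expected = np.where(
        shared, genome_mean * (plasmid_cn + 1.0), genome_mean * plasmid_cn
    )
    if noise.deterministic:
        return DepthTrack.from_dense(spec.name, expected)
    rng = noise.rng()
    depth = np.empty(length)
    for start in range(0, length, bin_size):
        end = min(start + bin_size, length)
        m = float(expected[start:end].mean())
        depth[start:end] = nb_draw(rng, np.array([m]), noise.dispersion)[0]
    return DepthTrack.from_dense(spec.name, depth)


# ---------------------------------------------------------------------------
# variant-call simulation


def simulate_variant_calls(
    n_samples: int,
    shared_mask: RegionMask,
    artifact_rate: float,
    unique_rate: float,
    introduced_alleles: Optional[Sequence[Mapping]] = None,
    seed: int = 0,
    layout: Optional[GenomeLayout] = None,
    n_artifact_sites: int = 3,
    n_unique_trials: int = 20,
) -> Tuple[Dict[str, List[VariantRecord]], dict]:
    """Plant recurrent shared-region artifacts and private true variants.

    Artifact variants are heterozygous, live inside ``shared_mask``, and
    recur in ``round(artifact_rate * n_samples)`` carriers (at least 1).
    True variants are homozygous, outside the mask, and private to one
    sample; each sample draws Binomial(``n_unique_trials``, ``unique_rate``)
    of them.  ``introduced_alleles`` rows (sequence, position, ref, alt,
    samples) are planted homozygous in their designated samples only.

    Returns per-sample record lists keyed ``s01``… plus a truth record.
    """
    if not 0 <= artifact_rate <= 1 or not 0 <= unique_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if artifact_rate > 0 and not shared_mask:
        raise ValueError("artifact_rate > 0 requires a non-empty shared mask")
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    calls: Dict[str, List[VariantRecord]] = {s: [] for s in sample_ids}
    bases = ["A", "C", "G", "T"]
    used_keys = set()

    def _alleles():
        ref, alt = rng.choice(4, size=2, replace=False)
        return bases[ref], bases[alt]

    # recurrent heterozygous artifacts inside the shared mask
    artifact_keys = []
    if artifact_rate > 0 and n_artifact_sites > 0:
        shared_ivs = list(shared_mask)
        n_carriers = max(1, round(artifact_rate * n_samples))
        for _ in range(n_artifact_sites):
            while True:
                seq, s, e = shared_ivs[rng.integers(len(shared_ivs))]
                pos = int(rng.integers(s, e)) + 1  # 1-based VCF position
                ref, alt = _alleles()
                key = (seq, pos, ref, alt)
                if key not in used_keys:
                    used_keys.add(key)
                    break
            carriers = rng.choice(n_samples, size=min(n_carriers, n_samples), replace=False)
            for c in sorted(carriers):
                calls[sample_ids[c]].append(
                    VariantRecord(sample_ids[c], seq, pos, ref, alt, "het")
                )
            artifact_keys.append(list(key))

    # sample-private homozygous true variants outside the mask
    private_keys: Dict[str, List[list]] = {s: [] for s in sample_ids}
    if unique_rate > 0:
        if layout is None:
            raise ValueError("layout required when unique_rate > 0")
        unmasked = []
        for name, length in layout.sequences:
            unmasked.extend(
                (name, s, e) for s, e in shared_mask.complement(name, length)
            )
        if not unmasked:
            raise ValueError("no unmasked sequence available for private variants")
        for sid in sample_ids:
            for _ in range(int(rng.binomial(n_unique_trials, unique_rate))):
                while True:
                    seq, s, e = unmasked[rng.integers(len(unmasked))]
                    pos = int(rng.integers(s, e)) + 1
                    ref, alt = _alleles()
                    key = (seq, pos, ref, alt)
                    if key not in used_keys:
                        used_keys.add(key)
                        break
                calls[sid].append(VariantRecord(sid, seq, pos, ref, alt, "hom"))
                private_keys[sid].append(list(key))

    # introduced alleles in designated samples only
    introduced_truth = []
    for row in introduced_alleles or []:
        key = (row["sequence"], int(row["position"]), row["ref"], row["alt"])
        designated = list(row["samples"])
        for sid in designated:
            if sid not in calls:
                raise ValueError(f"introduced allele names unknown sample {sid!r}")
            calls[sid].append(
                VariantRecord(sid, key[0], key[1], key[2], key[3], "hom")
            )
        introduced_truth.append({"key": list(key), "samples": designated})

    truth = {
        "artifact_keys": artifact_keys,
        "private_keys": private_keys,
        "introduced": introduced_truth,
        "seed": seed,
        "n_samples": n_samples,
    }
    return calls, truth


# ---------------------------------------------------------------------------
# qPCR plate simulation


def simulate_qpcr_plate(
    true_quantity_by_sample: Mapping[str, float],
    reference_ct: float = 20.0,
    ct_noise_sd: float = 0.1,
    n_triplicates: int = 3,
    n_bio_replicates: int = 1,
    seed: int = 0,
    target_gene: str = "target",
    reference_gene: str = "ref",
    efficiency: float = 1.0,
) -> Tuple[List[QpcrMeasurement], dict]:
    """Simulate Ct triplicates consistent with planted relative quantities.

    With perfect amplification efficiency (doubling per cycle), the target
    Ct is ``reference_ct - log2(quantity)`` plus Gaussian noise; the
    reference gene sits at ``reference_ct`` plus noise.  Technical
    replicates are independent.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    if n_triplicates < 1 or n_bio_replicates < 1:
        raise ValueError("replicate counts must be >= 1")
    base = 1.0 + efficiency  # 2.0 at perfect efficiency
    rng = np.random.default_rng(seed)
    measurements: List[QpcrMeasurement] = []
    for sample, quantity in true_quantity_by_sample.items():
        if quantity <= 0:
            raise ValueError(f"non-positive quantity for sample {sample!r}")
        target_mu = reference_ct - math.log(quantity, base)
        for rep in range(1, n_bio_replicates + 1):
            t_ct = target_mu + rng.normal(0.0, ct_noise_sd, n_triplicates) \
                if ct_noise_sd > 0 else np.full(n_triplicates, target_mu)
            r_ct = reference_ct + rng.normal(0.0, ct_noise_sd, n_triplicates) \
                if ct_noise_sd > 0 else np.full(n_triplicates, reference_ct)
            measurements.append(
                QpcrMeasurement(sample, rep, target_gene, "target", list(t_ct))
            )
            measurements.append(
                QpcrMeasurement(sample, rep, reference_gene, "reference", list(r_ct))
            )
    truth = {
        "true_quantity": dict(true_quantity_by_sample),
        "reference_ct": reference_ct,
        "ct_noise_sd": ct_noise_sd,
        "n_triplicates": n_triplicates,
        "n_bio_replicates": n_bio_replicates,
        "seed": seed,
    }
    return measurements, truth


# ---------------------------------------------------------------------------
# writers


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_vcf(records: Iterable[VariantRecord], sample_id: str, path) -> None:
    """Write a minimal single-sample VCF 4.2 (sorted by sequence, position)."""
    recs = sorted(records, key=lambda r: (r.sequence, r.position, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for seq in sorted({r.sequence for r in recs}):
            fh.write(f"##contig=<ID={seq}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for r in recs:
            gt = "0/1" if r.zygosity == "het" else "1/1"
            fh.write(
                f"{r.sequence}\t{r.position}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def write_qpcr_csv(measurements: Iterable[QpcrMeasurement], path) -> None:
    """Plate CSV with one row per technical Ct value."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "target", "role", "replicate", "ct"])
        for m in measurements:
            for ct in m.cts:
                writer.writerow([m.sample, m.gene, m.role, m.replicate, f"{ct:.4f}"])
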