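"""Cross-sample small-variant aggregation and recurrence screening.

Calls are aggregated by (sequence, position, ref, alt) key after
parsimony-trimming so indel keys are comparable across samples.
Heterozygous calls inside the plasmid/genome shared-sequence mask are
flagged as mapping artifacts; alleles deliberately introduced during
strain construction are flagged from an explicit table.  The recurrence
screen reports keys carried by more than two samples (``min_count=3``).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .regions import RegionMask

logger = logging.getLogger(__name__)

VariantKey = Tuple[str, int, str, str]

FLAG_SHARED_HET = "shared_region_het_artifact"
FLAG_INTRODUCED = "introduced_allele"
FLAG_BACKBONE = "backbone_region"


def trim_allele(position: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Parsimony-trim an allele pair: drop shared trailing bases, then
    shared leading bases (advancing the position), keeping >= 1 base each."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


@dataclass
class VariantRecord:
    """One sample-allele observation (VCF convention: 1-based position)."""

    sample: str
    sequence: str
    position: int
    ref: str
    alt: str
    zygosity: str  # "hom" or "het"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (VCF convention)")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be hom/het, got {self.zygosity!r}")
        self.position, self.ref, self.alt = trim_allele(
            self.position, self.ref, self.alt
        )

    @property
    def key(self) -> VariantKey:
        return (self.sequence, self.position, self.ref, self.alt)


@dataclass
class RecurrenceEntry:
    count: int
    carriers: List[str]
    flags: Set[str] = field(default_factory=set)


RecurrenceReport = Dict[VariantKey, RecurrenceEntry]


def read_calls(path, sample: Optional[str] = None) -> List[VariantRecord]:
    """Read VariantRecords from a VCF 4.x file (one record per sample-allele;
    multi-allelic sites decomposed).  Records without a called GT are
    skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns (GT required)")
    if sample is not None and len(samples) == 1:
        sample_names = [sample]
    else:
        sample_names = list(samples)
    records: List[VariantRecord] = []
    for v in vcf:
        gts = v.genotypes  # [[a0, a1, phased], ...] per sample
        for si, name in enumerate(sample_names):
            alleles = [a for a in gts[si][:-1] if a >= 0]
            if not alleles:
                logger.warning(
                    "%s: missing GT for %s at %s:%d; record skipped",
                    path, name, v.CHROM, v.POS,
                )
                continue
            carried = sorted({a for a in alleles if a > 0})
            for ai in carried:
                if ai - 1 >= len(v.ALT):
                    continue
                zyg = "hom" if all(a == ai for a in alleles) else "het"
                records.append(
                    VariantRecord(name, v.CHROM, v.POS, v.REF, v.ALT[ai - 1], zyg)
                )
    return records


def read_introduced_table(path) -> List[VariantKey]:
    """Read an introduced-allele CSV with columns sequence,position,ref,alt
    (extra annotation columns such as gene or cDNA change are ignored)."""
    keys: List[VariantKey] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sequence", "position", "ref", "alt"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            pos, ref, alt = trim_allele(
                int(row["position"]), row["ref"], row["alt"]
            )
            keys.append((row["sequence"], pos, ref, alt))
    return keys


def aggregate(
    records: Iterable[VariantRecord],
    shared_mask: Optional[RegionMask] = None,
    introduced: Optional[Iterable[VariantKey]] = None,
    backbone_mask: Optional[RegionMask] = None,
) -> RecurrenceReport:
    """Count carrier samples per variant key and attach artifact flags.

    Flags: ``shared_region_het_artifact`` for heterozygous calls inside the
    shared mask; ``introduced_allele`` for keys in the introduced table;
    ``backbone_region`` for keys inside the backbone annotation mask.
    The result is independent of record order.
    """
    introduced_set = set(introduced or [])
    report: RecurrenceReport = {}
    het_in_mask: Dict[VariantKey, bool] = {}
    for rec in records:
        entry = report.get(rec.key)
        if entry is None:
            entry = report[rec.key] = RecurrenceEntry(0, [])
        if rec.sample not in entry.carriers:
            entry.carriers.append(rec.sample)
            entry.count += 1
        in_mask = shared_mask is not None and shared_mask.contains(
            rec.sequence, rec.position - 1
        )
        if rec.zygosity == "het" and in_mask:
            het_in_mask[rec.key] = True
    for key, entry in report.items():
        entry.carriers.sort()
        entry.count = len(entry.carriers)
        if het_in_mask.get(key):
            entry.flags.add(FLAG_SHARED_HET)
        if key in introduced_set:
            entry.flags.add(FLAG_INTRODUCED)
        if backbone_mask is not None and backbone_mask.contains(key[0], key[1] - 1):
            entry.flags.add(FLAG_BACKBONE)
    return report


def recurrent(
    report: RecurrenceReport,
    min_count: int = 3,
    include_flagged: bool = False,
) -> List[VariantKey]:
    """Keys carried by at least ``min_count`` samples, excluding flagged keys
    unless ``include_flagged``.  The default encodes "observed more than two
    times"."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keys = [
        key
        for key, entry in report.items()
        if entry.count >= min_count and (include_flagged or not entry.flags)
    ]
    return sorted(keys)


def write_report_tsv(report: RecurrenceReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tposition\tref\talt\tcount\tflags\tcarriers\n")
        for key in sorted(report):
            entry = report[key]
            seq, pos, ref, alt = key
            fh.write(
                f"{seq}\t{pos}\t{ref}\t{alt}\t{entry.count}\t"
                f"{','.join(sorted(entry.flags)) or '.'}\t"
                f"{','.join(entry.carriers)}\n"
            )
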