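"""Ingestion and QC of per-read methylation patterns.

Reads arrive either as a collapsed pattern TSV (sample_id, region_id,
pattern, count[, allele_bases]) or as per-read CpG calls in the style of a
bisulfite aligner's CpG-context output, which are assembled into binary
patterns here.  A sample passes QC only if every panel region has at least
``min_depth`` reads (default 50, strict less-than excludes).  Control
samples are split 7:3 into training and validation sets at the sample level
so a donor's reads never straddle the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import (
    ReadPattern,
    RegionPanel,
    SampleReads,
    ValidationError,
    collapse_patterns,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "BismarkTally",
    "read_pattern_tsv",
    "write_pattern_tsv",
    "from_bismark_calls",
    "qc_filter",
    "split_controls",
]

MIN_DEPTH = 50

_METHYLATED = {"+", "Z", "1"}
_UNMETHYLATED = {"-", "z", "0"}


@dataclass(frozen=True)
class SplitSpec:
    """Sample-level train/validation split: 7:3 by default, seeded."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError(f"train_fraction must be in (0,1), got {self.train_fraction}")


def _parse_allele_bases(text: str) -> tuple[tuple[int, str], ...]:
    if not text or text in (".", "-"):
        return ()
    pairs = []
    for item in text.split(";"):
        pos, _, base = item.partition(":")
        pairs.append((int(pos), base))
    return tuple(pairs)


def _format_allele_bases(pairs: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{p}:{b}" for p, b in pairs) if pairs else "."


def read_pattern_tsv(path: str | Path, panel: RegionPanel | None = None) -> list[SampleReads]:
    """Load a collapsed pattern table.

    Columns (tab-separated, header optional): sample_id, region_id, pattern,
    count[, allele_bases].  Patterns are strings over {0,1}; identical rows
    merge additively.  When a panel is given, pattern lengths are checked
    against the region CpG counts.
    """
    path = Path(path)
    samples: dict[str, SampleReads] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample_id":  # header row
                continue
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected >= 4 columns, got {len(fields)}")
            sample_id, region_id, pattern, count = fields[:4]
            allele = _parse_allele_bases(fields[4]) if len(fields) > 4 else ()
            if set(pattern) - {"0", "1"}:
                raise ValidationError(
                    f"{path}:{lineno}: pattern {pattern!r} has characters outside {{0,1}}"
                )
            if panel is not None:
                region = panel.region(region_id)
                if len(pattern) != region.n_cpgs:
                    raise ValidationError(
                        f"{path}:{lineno}: pattern length {len(pattern)} != "
                        f"{region.n_cpgs} CpGs of region {region_id!r} "
                        f"(sample {sample_id!r})"
                    )
            rp = ReadPattern(
                sample_id=sample_id,
                region_id=region_id,
                bits=tuple(int(c) for c in pattern),
                count=int(count),
                allele_bases=allele,
            )
            samples.setdefault(sample_id, SampleReads(sample_id)).add(rp)
    out = list(samples.values())
    for s in out:
        s.collapse()
    return out


def write_pattern_tsv(samples: Iterable[SampleReads], path: str | Path) -> None:
    """Write the collapsed pattern table read back by :func:`read_pattern_tsv`."""
    with Path(path).open("w") as fh:
        fh.write("sample_id\tregion_id\tpattern\tcount\tallele_bases\n")
        for s in samples:
            for rid in sorted(s.patterns):
                for p in collapse_patterns(s.patterns[rid]):
                    fh.write(
                        f"{p.sample_id}\t{p.region_id}\t{p.pattern}\t{p.count}\t"
                        f"{_format_allele_bases(p.allele_bases)}\n"
                    )


@dataclass
class BismarkTally:
    """Bookkeeping for per-read call assembly."""

    reads_kept: int = 0
    reads_partial: int = 0
    calls_outside_panel: int = 0


def from_bismark_calls(
    calls: Iterable[tuple[str, str, str, int]],
    panel: RegionPanel,
    sample_id: str,
) -> tuple[SampleReads, BismarkTally]:
    """Assemble binary patterns from per-read CpG calls.

    ``calls`` yields (read_id, state_symbol, chrom, position) records, state
    '+'/'Z' methylated, '-'/'z' unmethylated, positions 1-based C positions.
    A read contributes only if it covers *all* CpGs of exactly one panel
    region; partially covering reads are discarded and tallied rather than
    imputed, and calls at positions outside the panel are tallied and
    skipped.
    """
    pos_index: dict[tuple[str, int], tuple[str, int]] = {}
    for region in panel:
        for i, pos in enumerate(region.cpg_positions):
            pos_index[(region.chrom, pos)] = (region.region_id, i)

    tally = BismarkTally()
    per_read: dict[str, dict[str, dict[int, int]]] = {}
    for read_id, state, chrom, position in calls:
        key = (chrom, int(position))
        if key not in pos_index:
            tally.calls_outside_panel += 1
            continue
        if state in _METHYLATED:
            bit = 1
        elif state in _UNMETHYLATED:
            bit = 0
        else:
            raise ValidationError(f"unknown methylation state symbol {state!r}")
        region_id, idx = pos_index[key]
        per_read.setdefault(read_id, {}).setdefault(region_id, {})[idx] = bit

    sample = SampleReads(sample_id)
    for read_id in sorted(per_read):
        regions = per_read[read_id]
        placed = False
        for region_id, bits_by_idx in regions.items():
            region = panel.region(region_id)
            if len(bits_by_idx) == region.n_cpgs:
                bits = tuple(bits_by_idx[i] for i in range(region.n_cpgs))
                sample.add(ReadPattern(sample_id, region_id, bits))
                placed = True
                break
        if not placed:
            tally.reads_partial += 1
        else:
            tally.reads_kept += 1
    sample.collapse()
    if tally.reads_partial:
        logger.info(
            "sample %s: %d read(s) discarded for incomplete region coverage",
            sample_id,
            tally.reads_partial,
        )
    return sample, tally


def qc_filter(
    samples: Iterable[SampleReads], panel: RegionPanel, min_depth: int = MIN_DEPTH
) -> tuple[list[SampleReads], list[SampleReads]]:
    """Exclude samples with fewer than ``min_depth`` reads on any panel region.

    The comparison is strict: depth 50 at the default threshold is kept,
    depth 49 excluded.  Returns (kept, excluded); qc_pass is set on each
    sample.
    """
    kept: list[SampleReads] = []
    excluded: list[SampleReads] = []
    for s in samples:
        ok = all(s.depth(r.region_id) >= min_depth for r in panel)
        s.qc_pass = ok
        (kept if ok else excluded).append(s)
    if excluded:
        logger.info(
            "QC: excluded %d of %d sample(s) with <%d reads on a region",
            len(excluded),
            len(excluded) + len(kept),
            min_depth,
        )
    return kept, excluded


def split_controls(
    controls: Sequence[SampleReads], spec: SplitSpec | None = None
) -> tuple[list[SampleReads], list[SampleReads]]:
    """Randomly partition control samples into training and validation sets.

    The split is at sample level so one donor's reads never appear on both
    sides.  Training size is ``round(train_fraction * n)`` (banker's
    rounding); deterministic for a fixed seed.
    """
    spec = spec or SplitSpec()
    controls = list(controls)
    if len(controls) < 2:
        raise ValidationError(f"need >= 2 control samples to split, got {len(controls)}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(controls))
    k = round(spec.train_fraction * len(controls))
    k = min(max(k, 1), len(controls) - 1)  # both sides non-empty
    train = [controls[i] for i in order[:k]]
    val = [controls[i] for i in order[k:]]
    return train, val
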