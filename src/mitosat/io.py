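"""Readers and writers: Genepop genotype files, FASTA alignments, sample maps.

The Genepop dialect accepted is the classic 2- or 3-digit one: a title line,
one locus name per line (or a single comma-separated line), ``Pop``
separators, then ``individual , 010012 023023 ...`` rows.  ``000``/``00``
allele codes are missing data.  FASTA parsing goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO

from .data import MISSING, DataError, GenotypeTable, HaplotypeAlignment, PopulationMap


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _decode_diploid(code: str, width: int, line_no: int) -> tuple[int, int]:
    if len(code) != 2 * width or not code.isdigit():
        raise ParseError(
            f"line {line_no}: allele code {code!r} is not {2 * width} digits"
        )
    a, b = int(code[:width]), int(code[width:])
    if (a == 0) != (b == 0):
        raise ParseError(
            f"line {line_no}: half-missing call {code!r} not supported"
        )
    return a, b


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Each ``Pop`` block becomes one population; its location label is the
    identifier of the first individual in the block (trailing digits and
    separators stripped, so ``RUN_01`` labels the block ``RUN``).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise ParseError("file too short to be Genepop")
    # locus names: one per line until the first Pop, or one comma-joined line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise ParseError("no 'Pop' separator found")
    if not loci:
        raise ParseError("no locus names before first 'Pop'")

    ids: list[str] = []
    locations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    block_label: str | None = None
    for line_no, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            block_label = None
            continue
        if "," not in line:
            raise ParseError(f"line {line_no}: expected 'id , alleles...'")
        ind_id, _, rest = line.partition(",")
        ind_id = ind_id.strip()
        codes = rest.split()
        if len(codes) != len(loci):
            raise DataError(
                f"line {line_no}: {len(codes)} loci found, {len(loci)} declared"
            )
        if width is None:
            width = len(codes[0]) // 2
            if width not in (2, 3):
                raise ParseError(
                    f"line {line_no}: allele width {width} (need 2- or 3-digit)"
                )
        if block_label is None:
            # "RUN_01" -> "RUN", "P1_000" -> "P1", "AUS2" -> "AUS2"
            if "_" in ind_id:
                block_label = ind_id.rsplit("_", 1)[0]
            else:
                block_label = ind_id.rstrip("0123456789-. ") or ind_id
        ids.append(ind_id)
        locations.append(block_label)
        rows.append([_decode_diploid(c, width, line_no) for c in codes])

    if not rows:
        raise ParseError("no individuals found")
    calls = np.array(rows, dtype=np.int32)
    return GenotypeTable(ids, locations, loci, calls)


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "mitosat export") -> None:
    width = 3 if int(table.calls.max(initial=0)) > 99 else 2
    out: list[str] = [title]
    out.extend(table.loci)
    order = table.location_set
    for loc in order:
        out.append("Pop")
        pop = table.population(loc)
        for i, ind in enumerate(pop.individual_ids):
            codes = []
            for l in range(pop.n_loci):
                a, b = pop.calls[i, l]
                codes.append(f"{a:0{width}d}{b:0{width}d}")
            out.append(f"{ind} , " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_sample_map(path: str | Path) -> PopulationMap:
    """Tab-separated ``id<TAB>location[<TAB>group]`` table."""
    ind_to_loc: dict[str, str] = {}
    loc_to_group: dict[str, str] = {}
    has_groups = False
    for line_no, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"line {line_no}: need id<TAB>location")
        ind, loc = parts[0].strip(), parts[1].strip()
        ind_to_loc[ind] = loc
        if len(parts) >= 3 and parts[2].strip():
            has_groups = True
            group = parts[2].strip()
            if loc_to_group.setdefault(loc, group) != group:
                raise ParseError(
                    f"line {line_no}: location {loc!r} mapped to two groups"
                )
    return PopulationMap(ind_to_loc, loc_to_group if has_groups else None)


def write_sample_map(pmap: PopulationMap, path: str | Path) -> None:
    out = []
    for ind, loc in pmap.individual_to_location.items():
        if pmap.location_to_group is not None:
            out.append(f"{ind}\t{loc}\t{pmap.location_to_group.get(loc, '')}")
        else:
            out.append(f"{ind}\t{loc}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_fasta_with_map(fasta: str | Path, sample_map: str | Path | PopulationMap) -> HaplotypeAlignment:
    """Load an aligned FASTA plus an id->location map into an alignment."""
    pmap = sample_map if isinstance(sample_map, PopulationMap) else read_sample_map(sample_map)
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ParseError(f"no FASTA records in {fasta}")
    locations = [pmap.location_of(i) for i in ids]
    return HaplotypeAlignment(ids, locations, seqs)


def write_fasta(alignment: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ind, seq in zip(alignment.individual_ids, alignment.sequences):
            fh.write(f">{ind}\n{seq}\n")


def filter_missing(table: GenotypeTable, max_missing_fraction: float = 0.5) -> GenotypeTable:
    """Drop individuals typed at too few loci.

    Individuals whose fraction of missing loci strictly exceeds
    ``max_missing_fraction`` (default 0.5) are removed. An empty result is
    allowed (a warning is raised, not an error).
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    keep = table.missing_fraction() <= max_missing_fraction
    if not keep.any():
        import warnings

        warnings.warn("all individuals removed by missing-data filter")
    return table.subset(keep)
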