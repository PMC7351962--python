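"""Readers and writers for genotype tables (CSV, GenePop) and group tables.

CSV layout: ``id,group_id,location,date,sex,age_class,mtdna,<locus>_a,<locus>_b,...``
with one row per individual and two columns per locus. An empty cell in either
allele column marks the locus missing; a value in only one of the two is a
half-typed locus and is rejected. GenePop files use the conventional 2- or
3-digit concatenated allele codes with ``00``/``000`` for missing.
"""

from __future__ import annotations

import csv
import re
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .core import (
    MISSING,
    BehaviourTally,
    GroupRecord,
    IndividualRecord,
    MultilocusGenotype,
)
from .errors import ArgumentError, ParseError, ValidationError

_META_COLUMNS = ["id", "group_id", "location", "date", "sex", "age_class", "mtdna"]


def _lenient_date(value) -> Optional[str]:
    """Best-effort date normalisation to ISO; unparseable or empty -> None."""
    if value is None:
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none"):
        return None
    ts = pd.to_datetime(s, errors="coerce")
    if ts is pd.NaT:
        return None
    return ts.date().isoformat()


def _cell(value) -> str:
    if value is None:
        return ""
    s = str(value).strip()
    return "" if s.lower() == "nan" else s


def parse_genotype_table(path, dialect: str = "csv") -> List[IndividualRecord]:
    """Parse a genotype table into individual records.

    ``dialect`` is ``"csv"`` (the native layout above) or ``"genepop"``.
    Duplicate ids and half-typed loci raise :class:`ValidationError`;
    malformed rows raise :class:`ParseError` naming the line.
    """
    if dialect == "csv":
        records = _parse_csv(path)
    elif dialect == "genepop":
        records = _parse_genepop(path)
    else:
        raise ArgumentError(f"unknown dialect {dialect!r}")
    seen = set()
    for r in records:
        if r.id in seen:
            raise ValidationError(f"duplicate id {r.id!r}")
        seen.add(r.id)
    return records


def _parse_csv(path) -> List[IndividualRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        for col in _META_COLUMNS[:1]:
            if col not in header:
                raise ParseError(f"{path}: missing required column {col!r}")
        locus_cols = [h for h in header if h.endswith("_a") or h.endswith("_b")]
        loci = []
        for h in locus_cols:
            name = h[:-2]
            if name not in loci:
                loci.append(name)
        for name in loci:
            if f"{name}_a" not in header or f"{name}_b" not in header:
                raise ParseError(f"{path}: locus {name!r} lacks paired _a/_b columns")
        idx = {h: i for i, h in enumerate(header)}

        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )

            def get(col, row=row):
                return _cell(row[idx[col]]) if col in idx else ""

            pairs = []
            for name in loci:
                a, b = get(f"{name}_a"), get(f"{name}_b")
                if a == "" and b == "":
                    pairs.append(MISSING)
                elif a == "" or b == "":
                    raise ValidationError(
                        f"{path}:{lineno}: half-typed locus {name!r}"
                    )
                else:
                    try:
                        pairs.append((int(a), int(b)))
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-integer allele at {name!r}"
                        ) from None
            if not get("id"):
                raise ParseError(f"{path}:{lineno}: empty id")
            records.append(
                IndividualRecord(
                    id=get("id"),
                    genotype=MultilocusGenotype(tuple(loci), tuple(pairs)),
                    mtdna=get("mtdna") or None,
                    sex=get("sex") or "unknown",
                    age_class=get("age_class") or "unknown",
                    group_id=get("group_id") or None,
                    location=get("location"),
                    date=_lenient_date(get("date")),
                )
            )
    return records


_GENEPOP_POP = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _parse_genepop(path) -> List[IndividualRecord]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty file")
    # line 1 is the title; locus names follow, one per line or comma-separated
    loci: List[str] = []
    i = 1
    while i < len(lines) and not _GENEPOP_POP.match(lines[i]):
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POP line found")
    if not loci:
        raise ParseError(f"{path}: no locus names before first POP")

    records = []
    pop = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _GENEPOP_POP.match(line):
            pop += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno + 1}: missing ',' separator")
        name, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}:{lineno + 1}: expected {len(loci)} genotypes, "
                f"got {len(tokens)}"
            )
        pairs = []
        for tok, locus in zip(tokens, loci):
            if len(tok) == 4:
                w = 2
            elif len(tok) == 6:
                w = 3
            else:
                raise ParseError(
                    f"{path}:{lineno + 1}: genotype {tok!r} at {locus!r} is "
                    "neither 4 nor 6 digits"
                )
            try:
                a, b = int(tok[:w]), int(tok[w:])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno + 1}: non-numeric genotype {tok!r}"
                ) from None
            if a == 0 and b == 0:
                pairs.append(MISSING)
            elif a == 0 or b == 0:
                raise ValidationError(
                    f"{path}:{lineno + 1}: half-typed locus {locus!r}"
                )
            else:
                pairs.append((a, b))
        records.append(
            IndividualRecord(
                id=name.strip(),
                genotype=MultilocusGenotype(tuple(loci), tuple(pairs)),
                group_id=f"pop{pop}" if pop > 1 else None,
            )
        )
    return records


def write_genotype_csv(records: Sequence[IndividualRecord], path) -> None:
    if not records:
        raise ArgumentError("no records to write")
    loci = records[0].genotype.loci
    header = _META_COLUMNS + [f"{l}_{s}" for l in loci for s in ("a", "b")]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in records:
            row = [
                r.id,
                r.group_id or "",
                r.location,
                r.date or "",
                "" if r.sex == "unknown" else r.sex,
                "" if r.age_class == "unknown" else r.age_class,
                r.mtdna or "",
            ]
            for pair in r.genotype.alleles:
                row.extend(["", ""] if pair is MISSING else [pair[0], pair[1]])
            w.writerow(row)


def parse_groups_csv(path) -> List[GroupRecord]:
    """Groups CSV: group_id,group_type,size_observed,member_ids,T,M,S,O.

    ``member_ids`` is semicolon-joined; T/M/S/O are behaviour tallies and may
    be blank (no behaviour data for that group).
    """
    groups = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                members = [
                    m.strip()
                    for m in _cell(row.get("member_ids")).split(";")
                    if m.strip()
                ]
                tallies = [_cell(row.get(k)) for k in ("T", "M", "S", "O")]
                behaviour = None
                if any(tallies):
                    behaviour = BehaviourTally(
                        *(int(t) if t else 0 for t in tallies)
                    )
                size = _cell(row.get("size_observed"))
                groups.append(
                    GroupRecord(
                        group_id=_cell(row.get("group_id")),
                        group_type=_cell(row.get("group_type")),
                        member_ids=members,
                        size_observed=int(size) if size else None,
                        behaviour=behaviour,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return groups


def write_groups_csv(groups: Iterable[GroupRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["group_id", "group_type", "size_observed", "member_ids", "T", "M", "S", "O"]
        )
        for g in groups:
            b = g.behaviour
            w.writerow(
                [
                    g.group_id,
                    g.group_type,
                    g.size_observed if g.size_observed is not None else "",
                    ";".join(g.member_ids),
                ]
                + (list(b.counts) if b is not None else ["", "", "", ""])
            )
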