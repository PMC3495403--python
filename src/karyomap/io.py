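"""Plain-text readers and writers (TSV, UTF-8, '.' decimal separator).

cM positions are written to 3 decimals; the population-specific flag is a
literal ``x`` or an empty field.  Order indices are 1-based in files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .karyotype import Karyotype, ChromosomePair, ChromosomeArm
from .maptable import COLUMNS, LinkageMapTable, MapValidationError
from .simulate import MISSING, Family, PedigreeGenotypes

__all__ = [
    "read_map_table",
    "write_map_table",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_pedigree_genotypes",
    "write_pedigree_genotypes",
    "read_karyotype",
    "write_karyotype",
    "write_events",
    "write_json",
]


def _looks_like_header(fields: list[str]) -> bool:
    try:
        float(fields[2])
        float(fields[3])
        return False
    except (ValueError, IndexError):
        return True


def read_map_table(path, validate: bool = True) -> LinkageMapTable:
    """Read an eight-column marker table; the header row is auto-detected.

    Raises on malformed rows (with the line number) and on violated map
    invariants (naming the offending group).
    """
    path = Path(path)
    rows = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 fields, got {len(fields)}")
            fields += [""] * (8 - len(fields))
            try:
                rows.append(
                    {
                        "marker": fields[0],
                        "group": fields[1],
                        "order": int(float(fields[2])),
                        "female_cM": float(fields[3]),
                        "male_cM": float(fields[4]),
                        "n_meioses": int(float(fields[5])) if fields[5].strip() else 0,
                        "accession": fields[6],
                        "population_specific": fields[7].strip().lower() == "x",
                    }
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=COLUMNS)
    return LinkageMapTable(df, validate=validate)


def write_map_table(table: LinkageMapTable, path, header: bool = True) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write("\t".join(COLUMNS) + "\n")
        for row in table.df.itertuples(index=False):
            fh.write(
                f"{row.marker}\t{row.group}\t{row.order}\t"
                f"{row.female_cM:.3f}\t{row.male_cM:.3f}\t{row.n_meioses}\t"
                f"{row.accession}\t{'x' if row.population_specific else ''}\n"
            )


# -- genotypes and pedigrees --------------------------------------------------

def write_genotypes(data: PedigreeGenotypes, path) -> None:
    """Individuals x markers matrix with {0,1,2,NA} entries."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(data.markers) + "\n")
        for ind, row in zip(data.individuals, data.genotypes):
            vals = "\t".join("NA" if v == MISSING else str(int(v)) for v in row)
            fh.write(f"{ind}\t{vals}\n")


def read_genotypes(path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    markers = list(df.columns[1:])
    individuals = df.iloc[:, 0].tolist()
    g = df.iloc[:, 1:].replace("NA", str(MISSING)).astype(int).to_numpy(dtype=np.int8)
    return individuals, markers, g


def write_pedigree(data: PedigreeGenotypes, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\tsire\tdam\tsex\tfamily\n")
        for fam in data.families:
            fh.write(f"{fam.sire}\t\t\t{data.sex.get(fam.sire, 'M')}\t{fam.name}\n")
            fh.write(f"{fam.dam}\t\t\t{data.sex.get(fam.dam, 'F')}\t{fam.name}\n")
            for off in fam.offspring:
                fh.write(f"{off}\t{fam.sire}\t{fam.dam}\t\t{fam.name}\n")


def read_pedigree(path) -> tuple[list[Family], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    families: dict[str, dict] = {}
    sex: dict[str, str] = {}
    for row in df.itertuples(index=False):
        fam = families.setdefault(row.family, {"sire": None, "dam": None, "offspring": []})
        if row.sire or row.dam:
            fam["offspring"].append(row.id)
            fam["sire"] = fam["sire"] or row.sire
            fam["dam"] = fam["dam"] or row.dam
        else:
            sex[row.id] = row.sex
            if row.sex == "M":
                fam["sire"] = row.id
            else:
                fam["dam"] = row.id
    return (
        [Family(name, f["sire"], f["dam"], f["offspring"]) for name, f in families.items()],
        sex,
    )


def write_pedigree_genotypes(data: PedigreeGenotypes, geno_path, ped_path) -> None:
    write_genotypes(data, geno_path)
    write_pedigree(data, ped_path)


def read_pedigree_genotypes(geno_path, ped_path) -> PedigreeGenotypes:
    individuals, markers, genotypes = read_genotypes(geno_path)
    families, sex = read_pedigree(ped_path)
    return PedigreeGenotypes(individuals, markers, genotypes, families, sex)


# -- karyotypes ---------------------------------------------------------------

def write_karyotype(karyotype: Karyotype, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("chromosome\tclass\tarms\tarm_lengths\n")
        for p in karyotype.pairs:
            arms = ",".join(a.name for a in p.arms)
            lengths = ",".join(f"{a.length:g}" for a in p.arms)
            fh.write(f"{p.name}\t{p.centromere_class}\t{arms}\t{lengths}\n")


def read_karyotype(path, label: str = "") -> Karyotype:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = []
    for row in df.itertuples(index=False):
        names = row.arms.split(",")
        lengths = [float(v) for v in row.arm_lengths.split(",")]
        arms = tuple(ChromosomeArm(n, l) for n, l in zip(names, lengths))
        pairs.append(ChromosomePair(row.chromosome, arms))
    return Karyotype(tuple(pairs), label=label)


# -- events and summaries -----------------------------------------------------

def write_events(events, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "event_type\treference_groups\tquery_groups\tjunction_lo\tjunction_hi\t"
            "orientation\tarchitecture\tresidue_group\n"
        )
        for ev in events:
            lo, hi = ev.junction if ev.junction is not None else ("", "")
            fh.write(
                f"{ev.event_type}\t{'+'.join(ev.groups_a)}\t{'+'.join(ev.groups_b)}\t"
                f"{lo if lo == '' else f'{lo:.3f}'}\t{hi if hi == '' else f'{hi:.3f}'}\t"
                f"{ev.orientation_label or ''}\t{ev.architecture}\t{ev.residue_group or ''}\n"
            )


def write_json(obj, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
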