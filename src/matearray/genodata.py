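"""Data model and I/O for codominant SSR progeny-array datasets.

A dataset is a collection of open-pollinated families (one sampled mother
tree plus the seeds collected from her) genotyped at a shared panel of
microsatellite loci, grouped into geographically referenced populations.

Allele codes are integer fragment sizes in base pairs.  Two sentinel codes
are reserved:

* ``NULL``  (−1): a non-amplifying (null) allele.  A true heterozygote
  ``(k, NULL)`` is scored on the electropherogram as the apparent
  homozygote ``(k, k)``; a true ``(NULL, NULL)`` individual is untyped.
* ``MISSING`` (0): no call (experimental missing data).

Genotypes are unordered pairs; the canonical form sorts the smaller code
first, so ``NULL`` (−1) always precedes a size code.

Two text dialects are supported: a tidy TSV (one row per individual per
locus) which is the native format, and a compact MLTR-style family-block
format used for interchange, in which each locus carries a 0/1 null-allele
status code.  Population coordinates and the locus registry travel in a
YAML sidecar (``<base>.meta.yaml``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

NULL: int = -1
MISSING: int = 0

Genotype = tuple[int, int]


class ParseError(ValueError):
    """Malformed genotype file (names the offending line)."""


class StructuralError(ValueError):
    """Internally inconsistent dataset (e.g. ragged locus lists)."""


def genotype(a: int, b: int) -> Genotype:
    """Canonical unordered genotype: smaller allele code first."""
    return (a, b) if a <= b else (b, a)


def is_untyped(g: Genotype | None) -> bool:
    return g is None or (g[0] == MISSING and g[1] == MISSING)


def observe_phenotype(g: Genotype, has_null: bool) -> Genotype:
    """Deterministic masking of a true genotype into the scored phenotype.

    At a null-carrying locus a ``(k, NULL)`` heterozygote is scored as the
    apparent homozygote ``(k, k)`` and ``(NULL, NULL)`` as untyped.  At a
    locus without nulls the genotype is returned unchanged.
    """
    a, b = genotype(*g)
    if not has_null:
        return (a, b)
    if a == NULL and b == NULL:
        return (MISSING, MISSING)
    if a == NULL:
        return (b, b)
    return (a, b)


@dataclass
class Locus:
    """One microsatellite locus: name, motif, size range and allele registry."""

    name: str
    repeat_motif: str = "GA"
    size_range: tuple[int, int] = (50, 500)
    alleles: list[int] = field(default_factory=list)
    has_null: bool = False

    @property
    def repeat_unit(self) -> int:
        """Length in bp of the repeat motif (2 for a dinucleotide)."""
        core = "".join(c for c in self.repeat_motif if c.isalpha())
        # compound motifs like "(GA)n(AG)n" keep the first unit
        unit = core.replace("N", "")
        for token in self.repeat_motif.replace(")", "(").split("("):
            if token and token.strip("nN").isalpha() and token.strip("nN"):
                return max(1, len(token.strip("nN")))
        return max(1, len(unit))

    def register(self, allele: int) -> None:
        if allele in (NULL, MISSING):
            return
        if allele not in self.alleles:
            self.alleles.append(allele)
            self.alleles.sort()

    def validate(self) -> None:
        lo, hi = self.size_range
        if len(set(self.alleles)) != len(self.alleles):
            raise StructuralError(f"duplicate allele codes at locus {self.name}")
        for a in self.alleles:
            if a in (NULL, MISSING):
                raise StructuralError(
                    f"reserved code {a} registered as allele at {self.name}"
                )
            if not lo <= a <= hi:
                raise StructuralError(
                    f"allele {a} outside size range {self.size_range} at {self.name}"
                )


@dataclass
class Family:
    """A progeny array: one mother tree and her open-pollinated seeds.

    ``maternal`` holds the scored maternal phenotype per locus (``None``
    when the mother was not genotyped); ``offspring`` is a list of
    per-locus phenotype lists, one entry per seed.
    """

    family_id: str
    maternal: list[Genotype | None]
    offspring: list[list[Genotype]]

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    def validate(self, n_loci: int) -> None:
        if self.n_offspring < 1:
            raise StructuralError(f"family {self.family_id} has no offspring")
        if len(self.maternal) != n_loci:
            raise StructuralError(
                f"family {self.family_id}: mother typed at {len(self.maternal)} "
                f"of {n_loci} loci"
            )
        for i, off in enumerate(self.offspring):
            if len(off) != n_loci:
                raise StructuralError(
                    f"family {self.family_id} offspring {i}: typed at "
                    f"{len(off)} of {n_loci} loci"
                )


@dataclass
class PopulationSample:
    name: str
    latitude: float = 0.0
    longitude: float = 0.0
    altitude: float = 0.0
    families: list[Family] = field(default_factory=list)

    @property
    def n_offspring(self) -> int:
        return sum(f.n_offspring for f in self.families)

    def validate(self, n_loci: int) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise StructuralError(f"{self.name}: latitude {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise StructuralError(f"{self.name}: longitude {self.longitude}")
        if not self.families:
            raise StructuralError(f"{self.name}: no families")
        for fam in self.families:
            fam.validate(n_loci)


@dataclass
class StudyDataset:
    """The unit the whole pipeline consumes: loci registry + populations."""

    loci: list[Locus]
    populations: list[PopulationSample]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population(self, name: str) -> PopulationSample:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(name)

    def validate(self, register_unseen: bool = True) -> None:
        for locus in self.loci:
            locus.validate()
        for pop in self.populations:
            pop.validate(self.n_loci)
        for pop in self.populations:
            for fam in pop.families:
                rows = [fam.maternal] + fam.offspring
                for row in rows:
                    for j, g in enumerate(row):
                        if g is None:
                            continue
                        for a in g:
                            if a in (NULL, MISSING):
                                continue
                            if a not in self.loci[j].alleles:
                                if register_unseen:
                                    warnings.warn(
                                        f"allele {a} at locus {self.loci[j].name} "
                                        "not in registry; adding",
                                        stacklevel=2,
                                    )
                                    self.loci[j].register(a)
                                else:
                                    raise StructuralError(
                                        f"unregistered allele {a} at locus "
                                        f"{self.loci[j].name}"
                                    )


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    allele_counts: dict[str, int]
    missing_rate: dict[str, float]
    incompatibilities: list[tuple[str, str, int, str]]  # pop, family, seed, locus


def _maternal_candidates(phen: Genotype | None, has_null: bool) -> list[Genotype]:
    """True maternal genotypes consistent with a scored maternal phenotype."""
    if phen is None or is_untyped(phen):
        return []  # unknown
    a, b = genotype(*phen)
    if has_null and a == b:
        return [(a, a), (NULL, a)]
    return [(a, b)]


def _offspring_candidates(phen: Genotype, has_null: bool) -> list[Genotype]:
    a, b = genotype(*phen)
    if has_null and a == b and a != MISSING:
        return [(a, a), (NULL, a)]
    if is_untyped(phen):
        return [(NULL, NULL)] if has_null else []
    return [(a, b)]


def mendelian_compatible(
    mother_phen: Genotype | None, off_phen: Genotype, has_null: bool
) -> bool:
    """Can any null-consistent true genotype pair link mother and offspring?"""
    mothers = _maternal_candidates(mother_phen, has_null)
    if not mothers:
        return True  # unknown mother constrains nothing
    offs = _offspring_candidates(off_phen, has_null)
    if not offs:
        return True  # untyped offspring constrains nothing
    for m in mothers:
        for o in offs:
            if o[0] in m or o[1] in m:
                return True
    return False


def validate_dataset(dataset: StudyDataset) -> ValidationReport:
    """Report-only screen: allele counts, missingness, Mendelian conflicts.

    A conflict is a seed whose phenotype shares no allele with its mother's
    phenotype at a locus, after accounting for the possibility that at a
    null-flagged locus an apparent homozygote hides a null allele.
    """
    dataset.validate()
    counts: dict[str, int] = {}
    miss: dict[str, float] = {}
    flags: list[tuple[str, str, int, str]] = []
    for j, locus in enumerate(dataset.loci):
        n_cells = 0
        n_missing = 0
        for pop in dataset.populations:
            for fam in pop.families:
                for k, off in enumerate(fam.offspring):
                    n_cells += 1
                    if is_untyped(off[j]):
                        n_missing += 1
                        continue
                    if not mendelian_compatible(fam.maternal[j], off[j], locus.has_null):
                        flags.append((pop.name, fam.family_id, k, locus.name))
        counts[locus.name] = len(locus.alleles)
        miss[locus.name] = n_missing / n_cells if n_cells else 0.0
    return ValidationReport(counts, miss, flags)


# ---------------------------------------------------------------------------
# I/O — tidy TSV (native) and MLTR-style family blocks (interchange)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "population\tfamily\trole\tindividual\tlocus\tallele_a\tallele_b"
)


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml") if path.suffix != ".tsv" else (
        path.with_name(path.stem + ".meta.yaml")
    )


def _write_meta(dataset: StudyDataset, path: Path) -> None:
    meta = {
        "loci": [
            {
                "name": loc.name,
                "repeat_motif": loc.repeat_motif,
                "size_range": list(loc.size_range),
                "alleles": list(loc.alleles),
                "has_null": bool(loc.has_null),
            }
            for loc in dataset.loci
        ],
        "populations": [
            {
                "name": pop.name,
                "latitude": float(pop.latitude),
                "longitude": float(pop.longitude),
                "altitude": float(pop.altitude),
            }
            for pop in dataset.populations
        ],
    }
    path.write_text(yaml.safe_dump(meta, sort_keys=False))


def _read_meta(path: Path) -> dict:
    return yaml.safe_load(path.read_text())


def write_progeny_dataset(
    dataset: StudyDataset, path: str | Path, format: str = "tsv"
) -> Path:
    """Serialize a dataset (plus its YAML metadata sidecar). Returns the path."""
    path = Path(path)
    if format == "tsv":
        _write_tsv(dataset, path)
    elif format == "mltr":
        write_mltr_format(dataset, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _write_meta(dataset, _meta_path(path))
    return path


def _fmt_g(g: Genotype | None) -> str:
    if g is None:
        return f"{MISSING}\t{MISSING}"
    a, b = genotype(*g)
    return f"{a}\t{b}"


def _write_tsv(dataset: StudyDataset, path: Path) -> None:
    lines = [_TSV_COLUMNS]
    for pop in dataset.populations:
        for fam in pop.families:
            for j, locus in enumerate(dataset.loci):
                lines.append(
                    f"{pop.name}\t{fam.family_id}\tmother\t{fam.family_id}-M\t"
                    f"{locus.name}\t{_fmt_g(fam.maternal[j])}"
                )
            for k, off in enumerate(fam.offspring):
                for j, locus in enumerate(dataset.loci):
                    lines.append(
                        f"{pop.name}\t{fam.family_id}\toffspring\t"
                        f"{fam.family_id}-O{k}\t{locus.name}\t{_fmt_g(off[j])}"
                    )
    path.write_text("\n".join(lines) + "\n")


def write_mltr_format(dataset: StudyDataset, path: str | Path) -> Path:
    """Write the MLTR-style dialect.

    Layout: a header ``n_populations n_loci``; one line of per-locus
    null-allele status codes (1 = null allele present, 0 = absent); then
    per population a ``P name lat lon alt n_families`` line followed by
    family blocks (``F id n_offspring``, one ``M`` maternal row, then one
    ``O`` row per seed, alleles as whitespace-separated pairs).
    """
    path = Path(path)
    out = [f"{len(dataset.populations)} {dataset.n_loci}"]
    out.append(" ".join("1" if loc.has_null else "0" for loc in dataset.loci))
    for pop in dataset.populations:
        out.append(
            f"P {pop.name} {pop.latitude:.6f} {pop.longitude:.6f} "
            f"{pop.altitude:.1f} {len(pop.families)}"
        )
        for fam in pop.families:
            out.append(f"F {fam.family_id} {fam.n_offspring}")
            row = " ".join(_fmt_g(g).replace("\t", " ") for g in fam.maternal)
            out.append(f"M {row}")
            for off in fam.offspring:
                row = " ".join(_fmt_g(g).replace("\t", " ") for g in off)
                out.append(f"O {row}")
    path.write_text("\n".join(out) + "\n")
    return path


def read_progeny_dataset(path: str | Path, format: str = "tsv") -> StudyDataset:
    """Read a dataset in either dialect; validates before returning.

    Unregistered alleles found in the genotype rows are added to the locus
    registry with a warning.  Structural problems (an individual typed at a
    different number of loci than the registry) raise :class:`StructuralError`;
    malformed rows raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    meta = _read_meta(_meta_path(path))
    loci = [
        Locus(
            name=m["name"],
            repeat_motif=m.get("repeat_motif", "GA"),
            size_range=tuple(m.get("size_range", (50, 500))),
            alleles=list(m.get("alleles", [])),
            has_null=bool(m.get("has_null", False)),
        )
        for m in meta["loci"]
    ]
    popmeta = {p["name"]: p for p in meta["populations"]}
    if format == "tsv":
        dataset = _read_tsv(path, loci, popmeta)
    elif format == "mltr":
        dataset = _read_mltr(path, loci)
        for pop in dataset.populations:
            pm = popmeta.get(pop.name)
            if pm:
                pop.latitude = float(pm["latitude"])
                pop.longitude = float(pm["longitude"])
                pop.altitude = float(pm["altitude"])
    else:
        raise ValueError(f"unknown format {format!r}")
    dataset.validate(register_unseen=True)
    return dataset


def _read_tsv(path: Path, loci: list[Locus], popmeta: dict) -> StudyDataset:
    locus_index = {loc.name: j for j, loc in enumerate(loci)}
    n_loci = len(loci)
    # individual -> per-locus genotype list
    pops: dict[str, PopulationSample] = {}
    rows: dict[tuple[str, str, str, str], list[Genotype | None]] = {}
    order: list[tuple[str, str, str, str]] = []
    with path.open() as fh:
        header = fh.readline()
        if header.strip().split("\t") != _TSV_COLUMNS.split("\t"):
            raise ParseError(f"{path}:1: unexpected header {header.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            popname, famid, role, indiv, locname, a_s, b_s = parts
            if locname not in locus_index:
                raise ParseError(f"{path}:{lineno}: unknown locus {locname!r}")
            try:
                a, b = int(a_s), int(b_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer allele") from exc
            key = (popname, famid, role, indiv)
            if key not in rows:
                rows[key] = [None] * n_loci
                order.append(key)
            rows[key][locus_index[locname]] = genotype(a, b)
    fams: dict[tuple[str, str], Family] = {}
    fam_order: list[tuple[str, str]] = []
    for key in order:
        popname, famid, role, indiv = key
        cells = rows[key]
        typed = [g for g in cells if g is not None]
        if len(typed) != n_loci:
            raise StructuralError(
                f"individual {indiv} typed at {len(typed)} of {n_loci} loci"
            )
        fkey = (popname, famid)
        if fkey not in fams:
            fams[fkey] = Family(famid, [None] * n_loci, [])
            fam_order.append(fkey)
        if role == "mother":
            fams[fkey].maternal = [g for g in cells]  # type: ignore[misc]
        elif role == "offspring":
            fams[fkey].offspring.append([g for g in cells])  # type: ignore[misc]
        else:
            raise ParseError(f"unknown role {role!r} for {indiv}")
    for fkey in fam_order:
        popname, _ = fkey
        if popname not in pops:
            pm = popmeta.get(popname, {})
            pops[popname] = PopulationSample(
                popname,
                float(pm.get("latitude", 0.0)),
                float(pm.get("longitude", 0.0)),
                float(pm.get("altitude", 0.0)),
            )
        pops[popname].families.append(fams[fkey])
    return StudyDataset(loci, list(pops.values()))


def _read_mltr(path: Path, loci: list[Locus]) -> StudyDataset:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    try:
        n_pops, n_loci = (int(x) for x in lines[0].split())
    except ValueError as exc:
        raise ParseError(f"{path}:1: bad header {lines[0]!r}") from exc
    if n_loci != len(loci):
        raise StructuralError(
            f"file declares {n_loci} loci but metadata registers {len(loci)}"
        )
    flags = lines[1].split()
    if len(flags) != n_loci:
        raise ParseError(f"{path}:2: expected {n_loci} null-status codes")
    for loc, fl in zip(loci, flags):
        loc.has_null = fl == "1"

    def parse_genotype_row(line: str, lineno: int) -> list[Genotype]:
        vals = line.split()[1:]
        if len(vals) != 2 * n_loci:
            raise ParseError(f"{path}:{lineno}: expected {2 * n_loci} alleles")
        try:
            ints = [int(v) for v in vals]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer allele") from exc
        return [genotype(ints[2 * j], ints[2 * j + 1]) for j in range(n_loci)]

    pops: list[PopulationSample] = []
    i = 2
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("P "):
            raise ParseError(f"{path}:{i + 1}: expected population line, got {line!r}")
        _, name, lat, lon, alt, n_fam = line.split()
        pop = PopulationSample(name, float(lat), float(lon), float(alt))
        i += 1
        for _ in range(int(n_fam)):
            if not lines[i].startswith("F "):
                raise ParseError(f"{path}:{i + 1}: expected family line")
            _, famid, n_off = lines[i].split()
            i += 1
            maternal = parse_genotype_row(lines[i], i + 1)
            i += 1
            fam = Family(
                famid,
                [None if is_untyped(g) else g for g in maternal],
                [],
            )
            for _ in range(int(n_off)):
                fam.offspring.append(parse_genotype_row(lines[i], i + 1))
                i += 1
            pop.families.append(fam)
        pops.append(pop)
    return StudyDataset(loci, pops)


def datasets_equal(a: StudyDataset, b: StudyDataset) -> bool:
    """Structural equality (canonical genotype order; None ≡ untyped mother)."""

    def norm_m(g):
        return None if g is None or is_untyped(g) else genotype(*g)

    if [loc.name for loc in a.loci] != [loc.name for loc in b.loci]:
        return False
    if [loc.has_null for loc in a.loci] != [loc.has_null for loc in b.loci]:
        return False
    if len(a.populations) != len(b.populations):
        return False
    for pa, pb in zip(a.populations, b.populations):
        if (pa.name, len(pa.families)) != (pb.name, len(pb.families)):
            return False
        for fa, fb in zip(pa.families, pb.families):
            if fa.family_id != fb.family_id:
                return False
            if [norm_m(g) for g in fa.maternal] != [norm_m(g) for g in fb.maternal]:
                return False
            if [[genotype(*g) for g in o] for o in fa.offspring] != [
                [genotype(*g) for g in o] for o in fb.offspring
            ]:
                return False
    return True
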