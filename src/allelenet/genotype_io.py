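"""Genotype matrices, population panels, and the file formats that carry them.

The in-memory model is deliberately small: a :class:`GenotypeMatrix` holds an
``individuals x SNPs`` array of allele-B dosages (0, 1, 2, or :data:`MISSING`)
together with per-SNP annotation records, and a :class:`PopulationPanel` maps
individuals to populations and populations to a representative latitude.
Missing genotypes are carried through every stage exactly as observed — no
imputation is performed anywhere in this package, because imputed calls
inflate linkage-disequilibrium estimates.

Supported on-disk formats:

``tabular``
    A simple genotype table: a header row of SNP identifiers (first column
    ``individual``), one row per individual, calls written as two-character
    allele strings (``AA``, ``Aa`` ...), ``NN`` or ``--`` for missing.  SNP
    annotations (chromosome, position, gene, allele symbols) live in an
    optional sidecar ``<path>.snps.tsv`` which the reader picks up
    automatically.
``plink-text``
    PLINK ``.ped``/``.map`` text pair (alleles coded as symbols, ``0`` for
    missing).
``vcf``
    VCF with one sample column per individual; REF is ``allele_a`` and the
    single ALT is ``allele_b``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "PopulationPanel",
    "GenotypeFormatError",
    "PanelError",
    "read_genotypes",
    "write_genotypes",
    "read_panel",
    "write_panel",
]

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_MISSING_CALLS = {"NN", "--", "??", "00"}


class GenotypeFormatError(ValueError):
    """A genotype file violates the biallelic-SNP data model."""


class PanelError(ValueError):
    """A population panel is incomplete or out of range."""


@dataclass(frozen=True)
class SnpRecord:
    """Identity and annotation of one biallelic SNP.

    ``allele_a``/``allele_b`` are single-character symbols; dosage always
    counts copies of ``allele_b``.  Position is 1-based and annotation only —
    no computation in this package uses physical coordinates.
    """

    snp_id: str
    chromosome: str = ""
    position: int = 0
    gene: str = ""
    allele_a: str = "A"
    allele_b: str = "a"

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise GenotypeFormatError(
                f"SNP {self.snp_id}: alleles must differ (got {self.allele_a!r} twice)"
            )
        if len(self.allele_a) != 1 or len(self.allele_b) != 1:
            raise GenotypeFormatError(
                f"SNP {self.snp_id}: allele symbols must be single characters"
            )
        if self.position < 0:
            raise GenotypeFormatError(f"SNP {self.snp_id}: negative position")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)


@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes for a cohort.

    Parameters
    ----------
    snps
        Ordered SNP annotation records; ``snp_id`` must be unique.
    individuals
        Ordered individual identifiers.
    dosage
        ``(n_individuals, n_snps)`` integer array counting copies of each
        SNP's ``allele_b``; entries in ``{0, 1, 2}`` or :data:`MISSING`.
    """

    snps: list[SnpRecord]
    individuals: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_ind, n_snp = self.dosage.shape
        if n_ind != len(self.individuals) or n_snp != len(self.snps):
            raise GenotypeFormatError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeFormatError(f"duplicate SNP identifiers: {dupes}")
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"invalid dosage {self.dosage[i, j]} for individual "
                f"{self.individuals[i]!r} at SNP {ids[j]!r}"
            )
        if n_ind and (self.dosage == MISSING).all(axis=0).any():
            j = int(np.argwhere((self.dosage == MISSING).all(axis=0))[0])
            raise GenotypeFormatError(f"SNP {ids[j]!r} has no scored genotypes")
        self._index = {s: k for k, s in enumerate(ids)}

    # -- accessors ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        return self._index[snp_id]

    def snp(self, snp_id: str) -> SnpRecord:
        return self.snps[self._index[snp_id]]

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP (copies of ``allele_b``)."""
        return self.dosage[:, self._index[snp_id]]

    def gene_map(self) -> dict[str, str]:
        return {s.snp_id: s.gene for s in self.snps}

    # -- transforms --------------------------------------------------------

    def reorient(self, snp_id: str) -> "GenotypeMatrix":
        """Swap allele_a/allele_b at one SNP (dosage becomes ``2 - dosage``).

        Reorientation relabels the combination axis of downstream CCC
        vectors but changes no statistic's value set.
        """
        j = self._index[snp_id]
        snps = list(self.snps)
        snps[j] = replace(snps[j], allele_a=snps[j].allele_b, allele_b=snps[j].allele_a)
        dosage = self.dosage.copy()
        col = dosage[:, j]
        scored = col != MISSING
        col[scored] = 2 - col[scored]
        return GenotypeMatrix(snps, list(self.individuals), dosage)

    def subset_individuals(self, keep: Sequence[str]) -> "GenotypeMatrix":
        order = {ind: k for k, ind in enumerate(self.individuals)}
        rows = [order[i] for i in keep]
        return GenotypeMatrix(list(self.snps), list(keep), self.dosage[rows])

    def call_strings(self) -> np.ndarray:
        """Genotype calls as two-character allele strings (``NN`` missing)."""
        out = np.empty((self.n_individuals, self.n_snps), dtype=object)
        for j, s in enumerate(self.snps):
            lut = {
                0: s.allele_a * 2,
                1: s.allele_a + s.allele_b,
                2: s.allele_b * 2,
                MISSING: "NN",
            }
            out[:, j] = [lut[int(d)] for d in self.dosage[:, j]]
        return out


@dataclass
class PopulationPanel:
    """Individual-to-population assignment plus one latitude per population.

    Latitude is a single representative value per population, in signed
    degrees, the covariate for cline regressions.
    """

    assignment: dict[str, str]
    latitude: dict[str, float]

    def __post_init__(self) -> None:
        for pop, lat in self.latitude.items():
            if not -90.0 <= float(lat) <= 90.0:
                raise PanelError(f"population {pop!r}: latitude {lat} outside [-90, 90]")
        missing = {p for p in self.assignment.values() if p not in self.latitude}
        if missing:
            raise PanelError(f"populations without a latitude: {sorted(missing)}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop, None)
        return list(seen)

    def individuals_of(self, population: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == population]

    def sample_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for pop in self.assignment.values():
            sizes[pop] = sizes.get(pop, 0) + 1
        return sizes

    def pool(self, mapping: Mapping[str, str]) -> "PopulationPanel":
        """Merge populations, e.g. ``{"Ethiopian": "Sub-Saharan"}``.

        The target label keeps its own latitude; each source label's
        individuals are relabelled and its latitude entry dropped.
        """
        for src, dst in mapping.items():
            if dst not in self.latitude:
                raise PanelError(f"pooling target {dst!r} has no latitude")
        assignment = {
            ind: mapping.get(pop, pop) for ind, pop in self.assignment.items()
        }
        latitude = {
            pop: lat for pop, lat in self.latitude.items() if pop not in mapping
        }
        return PopulationPanel(assignment, latitude)


# ---------------------------------------------------------------------------
# tabular dialect


def _read_tabular(path: Path, snp_table: Path | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("individual")
    snp_ids = list(df.columns)

    sidecar = snp_table if snp_table is not None else Path(str(path) + ".snps.tsv")
    annot: dict[str, SnpRecord] = {}
    if sidecar is not None and Path(sidecar).exists():
        sdf = pd.read_csv(sidecar, sep="\t", dtype=str).fillna("")
        for _, row in sdf.iterrows():
            annot[row["snp_id"]] = SnpRecord(
                snp_id=row["snp_id"],
                chromosome=row.get("chromosome", ""),
                position=int(row["position"]) if row.get("position", "") else 0,
                gene=row.get("gene", ""),
                allele_a=row["allele_a"],
                allele_b=row["allele_b"],
            )

    snps: list[SnpRecord] = []
    calls = df.to_numpy(dtype=object)
    dosage = np.full(calls.shape, MISSING, dtype=np.int8)
    for j, sid in enumerate(snp_ids):
        col = calls[:, j]
        observed: list[str] = []
        for c in col:
            if isinstance(c, str) and c not in _MISSING_CALLS:
                observed.extend(c)
        symbols = sorted(set(observed))
        if sid in annot:
            rec = annot[sid]
            extra = set(symbols) - set(rec.alleles)
            if extra:
                raise GenotypeFormatError(
                    f"SNP {sid!r}: call uses symbol(s) {sorted(extra)} not among "
                    f"declared alleles {rec.alleles}"
                )
        else:
            if len(symbols) > 2:
                raise GenotypeFormatError(
                    f"SNP {sid!r} is multi-allelic: observed alleles {symbols}"
                )
            a = symbols[0] if symbols else "A"
            b = symbols[1] if len(symbols) > 1 else ("N" if a != "N" else "?")
            rec = SnpRecord(snp_id=sid, allele_a=a, allele_b=b)
        snps.append(rec)
        for i, c in enumerate(col):
            if not isinstance(c, str) or c in _MISSING_CALLS:
                continue
            if len(c) != 2:
                raise GenotypeFormatError(
                    f"individual {df.index[i]!r}, SNP {sid!r}: malformed call {c!r}"
                )
            d = 0
            for sym in c:
                if sym == rec.allele_b:
                    d += 1
                elif sym != rec.allele_a:
                    raise GenotypeFormatError(
                        f"individual {df.index[i]!r}, SNP {sid!r}: unknown allele "
                        f"symbol {sym!r} (expected {rec.allele_a!r}/{rec.allele_b!r})"
                    )
            dosage[i, j] = d
    return GenotypeMatrix(snps, list(df.index), dosage)


def _write_tabular(path: Path, matrix: GenotypeMatrix) -> None:
    calls = matrix.call_strings()
    df = pd.DataFrame(calls, index=matrix.individuals, columns=matrix.snp_ids)
    df.index.name = "individual"
    df.to_csv(path, sep="\t")
    sdf = pd.DataFrame(
        [
            {
                "snp_id": s.snp_id,
                "chromosome": s.chromosome,
                "position": s.position,
                "gene": s.gene,
                "allele_a": s.allele_a,
                "allele_b": s.allele_b,
            }
            for s in matrix.snps
        ]
    )
    sdf.to_csv(str(path) + ".snps.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK text dialect


def _plink_paths(path: Path) -> tuple[Path, Path]:
    base = Path(str(path)[: -len(path.suffix)] if path.suffix in {".ped", ".map"} else str(path))
    return Path(str(base) + ".ped"), Path(str(base) + ".map")


def _read_plink_text(path: Path) -> GenotypeMatrix:
    ped_path, map_path = _plink_paths(path)
    mdf = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position"],
        dtype={"chromosome": str, "snp_id": str},
    )
    if mdf["snp_id"].duplicated().any():
        dupes = sorted(mdf.loc[mdf["snp_id"].duplicated(), "snp_id"])
        raise GenotypeFormatError(f"duplicate SNP identifiers in .map: {dupes}")
    n_snps = len(mdf)

    individuals: list[str] = []
    allele_calls: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeFormatError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields; expected {2 * n_snps}"
                )
            individuals.append(parts[1])
            g = parts[6:]
            allele_calls.append([(g[2 * j], g[2 * j + 1]) for j in range(n_snps)])

    snps: list[SnpRecord] = []
    dosage = np.full((len(individuals), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        symbols = sorted(
            {a for row in allele_calls for a in row[j] if a != "0"}
        )
        if len(symbols) > 2:
            raise GenotypeFormatError(
                f"SNP {mdf.snp_id[j]!r} is multi-allelic: observed alleles {symbols}"
            )
        a = symbols[0] if symbols else "A"
        b = symbols[1] if len(symbols) > 1 else ("N" if a != "N" else "?")
        snps.append(
            SnpRecord(
                snp_id=mdf.snp_id[j],
                chromosome=str(mdf.chromosome[j]),
                position=int(mdf.position[j]),
                allele_a=a,
                allele_b=b,
            )
        )
        for i, row in enumerate(allele_calls):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == b) + (a2 == b)
    return GenotypeMatrix(snps, individuals, dosage)


def _write_plink_text(path: Path, matrix: GenotypeMatrix) -> None:
    ped_path, map_path = _plink_paths(path)
    with open(map_path, "w") as fh:
        for s in matrix.snps:
            fh.write(f"{s.chromosome or 0}\t{s.snp_id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(matrix.individuals):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for j, s in enumerate(matrix.snps):
                d = int(matrix.dosage[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [s.allele_a, s.allele_a]
                elif d == 1:
                    fields += [s.allele_a, s.allele_b]
                else:
                    fields += [s.allele_b, s.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        sid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise GenotypeFormatError(
                f"SNP {sid!r} is not a biallelic SNP (REF={rec.REF}, ALT={rec.ALT})"
            )
        if sid in seen:
            raise GenotypeFormatError(f"duplicate SNP identifier {sid!r} in VCF")
        seen.add(sid)
        gene = ""
        try:
            raw = rec.INFO.get("GENE")
            if raw is not None:
                gene = str(raw)
        except Exception:
            pass
        snps.append(
            SnpRecord(
                snp_id=sid,
                chromosome=rec.CHROM,
                position=rec.POS,
                gene=gene,
                allele_a=rec.REF,
                allele_b=rec.ALT[0],
            )
        )
        col = np.full(len(individuals), MISSING, dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                continue
            col[i] = (a0 == 1) + (a1 == 1)
        columns.append(col)
    return GenotypeMatrix(snps, individuals, np.column_stack(columns))


def _write_vcf(path: Path, matrix: GenotypeMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, s in enumerate(matrix.snps):
            info = f"GENE={s.gene}" if s.gene else "."
            cells = [gt[int(d)] for d in matrix.dosage[:, j]]
            fh.write(
                f"{s.chromosome or '.'}\t{s.position or 1}\t{s.snp_id}\t"
                f"{s.allele_a}\t{s.allele_b}\t.\t.\t{info}\tGT\t" + "\t".join(cells) + "\n"
            )


_READERS = {"tabular": _read_tabular, "plink-text": _read_plink_text, "vcf": _read_vcf}
_WRITERS = {"tabular": _write_tabular, "plink-text": _write_plink_text, "vcf": _write_vcf}


def read_genotypes(path: str | os.PathLike, format: str = "tabular") -> GenotypeMatrix:
    """Read a genotype matrix; ``format`` is one of tabular/plink-text/vcf."""
    if format not in _READERS:
        raise ValueError(f"unknown genotype format {format!r}")
    return _READERS[format](Path(path))


def write_genotypes(
    path: str | os.PathLike, matrix: GenotypeMatrix, format: str = "tabular"
) -> None:
    if format not in _WRITERS:
        raise ValueError(f"unknown genotype format {format!r}")
    _WRITERS[format](Path(path), matrix)


def read_panel(
    path: str | os.PathLike, pool: Mapping[str, str] | None = None
) -> PopulationPanel:
    """Read a TSV of (individual, population, latitude); optionally pool labels."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "population": str})
    for col in ("individual", "population", "latitude"):
        if col not in df.columns:
            raise PanelError(f"panel file missing column {col!r}")
    if df["population"].isna().any():
        bad = df.loc[df["population"].isna(), "individual"].tolist()
        raise PanelError(f"individuals without a population: {bad}")
    if df["latitude"].isna().any():
        bad = sorted(set(df.loc[df["latitude"].isna(), "population"]))
        raise PanelError(f"populations without a latitude: {bad}")
    assignment = dict(zip(df["individual"], df["population"]))
    latitude: dict[str, float] = {}
    for pop, grp in df.groupby("population"):
        lats = set(grp["latitude"].astype(float))
        if len(lats) != 1:
            raise PanelError(f"population {pop!r} has conflicting latitudes {sorted(lats)}")
        latitude[pop] = lats.pop()
    panel = PopulationPanel(assignment, latitude)
    if pool:
        panel = panel.pool(pool)
    return panel


def write_panel(path: str | os.PathLike, panel: PopulationPanel) -> None:
    rows = [
        {"individual": ind, "population": pop, "latitude": panel.latitude[pop]}
        for ind, pop in panel.assignment.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
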