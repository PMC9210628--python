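"""Pathway gene-set registry with coding-length annotation.

A pathway here is a plain gene set (no topology) together with the coding
sequence length of each member gene in base pairs.  The coding length is the
denominator of the per-megabase mutation burden statistic, so it is supplied
explicitly by the user (two-column TSV or BED) rather than derived from an
annotation file inside the pipeline.

Gene identity is an exact, case-sensitive symbol match; no alias resolution
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class RegistryError(ValueError):
    """Raised for malformed gene-set or length inputs."""


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set with per-gene coding lengths.

    Parameters
    ----------
    name
        Pathway identifier, unique within a collection.
    genes
        Member gene symbols (non-empty).
    coding_length_bp
        Map gene -> coding sequence length in base pairs (> 0). Must cover
        every member gene.
    """

    name: str
    genes: frozenset[str]
    coding_length_bp: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.genes:
            raise RegistryError(f"pathway {self.name!r}: empty gene set")
        missing = sorted(g for g in self.genes if g not in self.coding_length_bp)
        if missing:
            raise RegistryError(
                f"pathway {self.name!r}: missing coding length for "
                f"{len(missing)} gene(s): {', '.join(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
        bad = sorted(g for g in self.genes if self.coding_length_bp[g] <= 0)
        if bad:
            raise RegistryError(
                f"pathway {self.name!r}: non-positive coding length for: "
                + ", ".join(bad[:10])
            )

    @property
    def total_coding_length_bp(self) -> int:
        return sum(self.coding_length_bp[g] for g in self.genes)

    @property
    def total_coding_length_mb(self) -> float:
        return self.total_coding_length_bp / 1e6

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class PathwayCollection:
    """An ordered collection of pathways with derived shared-gene structure."""

    pathways: list[PathwaySet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegistryError(f"duplicate pathway names: {', '.join(dupes)}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    @property
    def shared_genes(self) -> dict[str, set[str]]:
        """Genes belonging to more than one pathway, mapped to those pathways."""
        membership: dict[str, set[str]] = {}
        for p in self.pathways:
            for g in p.genes:
                membership.setdefault(g, set()).add(p.name)
        return {g: s for g, s in membership.items() if len(s) > 1}

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return out

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> PathwaySet:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    def drop_shared_genes(self) -> "PathwayCollection":
        """Restrict every pathway to genes belonging to exactly one pathway.

        Used for the sensitivity analysis that removes cross-talk between
        overlapping gene sets.  Raises if any pathway would be left empty.
        Idempotent: applying it twice equals applying it once.
        """
        shared = set(self.shared_genes)
        out = []
        for p in self.pathways:
            keep = p.genes - shared
            if not keep:
                raise RegistryError(
                    f"pathway {p.name!r} empty after removing shared genes"
                )
            out.append(
                PathwaySet(
                    name=p.name,
                    genes=frozenset(keep),
                    coding_length_bp={g: p.coding_length_bp[g] for g in keep},
                )
            )
        return PathwayCollection(out)


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Read per-gene coding lengths from a 2-column TSV or a BED file.

    TSV: ``gene<TAB>length_bp``.  BED: half-open 0-based intervals with the
    gene name in column 4; interval lengths are summed per gene so a gene
    split over several exon rows accumulates its full coding length.
    """
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) >= 4 and parts[1].isdigit() and parts[2].isdigit():
                start, end, gene = int(parts[1]), int(parts[2]), parts[3]
                if end <= start:
                    raise RegistryError(
                        f"{path.name}:{lineno}: empty/inverted interval"
                    )
                lengths[gene] = lengths.get(gene, 0) + (end - start)
            elif len(parts) >= 2:
                gene, bp = parts[0], parts[1]
                try:
                    bp_i = int(bp)
                except ValueError as exc:
                    raise RegistryError(
                        f"{path.name}:{lineno}: non-integer length {bp!r}"
                    ) from exc
                lengths[gene] = lengths.get(gene, 0) + bp_i
            else:
                raise RegistryError(f"{path.name}:{lineno}: unparsable line")
    return lengths


def load_gmt(path: str | Path, lengths: str | Path | Mapping[str, int]) -> PathwayCollection:
    """Load gene sets from a GMT file and attach coding lengths.

    GMT lines are tab-separated ``name<TAB>description<TAB>gene...``.  Every
    gene in every set must have a length annotation; genes missing from the
    length map raise an error listing them.
    """
    if isinstance(lengths, (str, Path)):
        length_map = read_gene_lengths(lengths)
    else:
        length_map = dict(lengths)

    pathways: list[PathwaySet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RegistryError(
                    f"{Path(path).name}:{lineno}: GMT line needs name, "
                    "description and at least one gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise RegistryError(f"{Path(path).name}:{lineno}: empty set {name!r}")
            missing = sorted(g for g in genes if g not in length_map)
            if missing:
                raise RegistryError(
                    f"set {name!r}: no length annotation for "
                    f"{len(missing)} gene(s): {', '.join(missing[:10])}"
                    + ("..." if len(missing) > 10 else "")
                )
            pathways.append(
                PathwaySet(
                    name=name,
                    genes=frozenset(genes),
                    coding_length_bp={g: length_map[g] for g in genes},
                )
            )
    return PathwayCollection(pathways)


def write_gmt(coll: PathwayCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for p in coll.pathways:
            fh.write("\t".join([p.name, description, *sorted(p.genes)]) + "\n")


def write_gene_lengths(coll: PathwayCollection, path: str | Path) -> None:
    merged: dict[str, int] = {}
    for p in coll.pathways:
        merged.update(p.coding_length_bp)
    with open(path, "w") as fh:
        for g in sorted(merged):
            fh.write(f"{g}\t{merged[g]}\n")
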