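"""Domain types and file I/O shared by all analysis stages.

The package works on diploid microsatellite genotypes (allele calls as
fragment sizes in base pairs) read from and written to Genepop files, and
on mtDNA haplotype alignments read from FASTA.  Alleles are stored as
integer sizes in bp; internally the mutation machinery converts them to
repeat counts as ``(size - min_len) / motif_bp``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("msatpop")

#: Internal sentinel for a missing allele call (Genepop "000"/"00").
MISSING = 0

__all__ = [
    "MISSING",
    "LocusSpec",
    "GenotypeMatrix",
    "AlleleFreqTable",
    "HaplotypeAlignment",
    "GenepopParseError",
    "GenepopDialectError",
    "GenepopEncodingError",
    "read_genepop",
    "write_genepop",
    "allele_freqs",
    "read_fasta",
    "write_fasta",
    "configure_logging",
    "load_run_config",
    "dump_run_config",
]


def configure_logging(level: int = logging.INFO) -> logging.Logger:
    """Attach a plain-text handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


def load_run_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def dump_run_config(cfg: dict, path) -> None:
    from . import __version__

    cfg = dict(cfg)
    cfg.setdefault("msatpop_version", __version__)
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusSpec:
    """A microsatellite locus: size frame and mutation model.

    Parameters
    ----------
    motif_bp
        Base pairs per repeat unit.
    min_len, max_len
        Allele size bounds in bp; the allele lattice is
        ``min_len, min_len + motif_bp, ..., max_len``.
    mu
        Mutation rate per generation per gene copy.
    p_gsm
        Geometric-step parameter of the generalized stepwise model;
        0 recovers the strict single-step model.
    """

    name: str
    motif_bp: int = 2
    min_len: int = 20
    max_len: int = 40
    mu: float = 3.5e-4
    p_gsm: float = 0.22

    def __post_init__(self):
        if self.motif_bp < 1:
            raise ValueError(f"{self.name}: motif_bp must be >= 1")
        if not self.min_len < self.max_len:
            raise ValueError(f"{self.name}: need min_len < max_len")
        if (self.max_len - self.min_len) % self.motif_bp != 0:
            raise ValueError(
                f"{self.name}: allele span {self.max_len - self.min_len} not a "
                f"multiple of motif_bp={self.motif_bp}"
            )
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"{self.name}: mu must lie in [0, 1)")
        if not 0.0 <= self.p_gsm < 1.0:
            raise ValueError(f"{self.name}: p_gsm must lie in [0, 1)")

    @property
    def n_states(self) -> int:
        """Number of allele states on the size lattice."""
        return (self.max_len - self.min_len) // self.motif_bp + 1

    def size_to_repeat(self, size):
        return (np.asarray(size) - self.min_len) // self.motif_bp

    def repeat_to_size(self, repeat):
        return self.min_len + np.asarray(repeat) * self.motif_bp


def default_loci(n_loci: int = 12, *, motif_bp: int = 2, min_len: int = 20,
                 max_len: int = 40, mu: float = 3.5e-4,
                 p_gsm: float = 0.22) -> list[LocusSpec]:
    """A panel of identically-framed dinucleotide loci (L1..Ln)."""
    return [
        LocusSpec(f"L{i + 1}", motif_bp=motif_bp, min_len=min_len,
                  max_len=max_len, mu=mu, p_gsm=p_gsm)
        for i in range(n_loci)
    ]


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls, individuals x loci.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` holding allele sizes
    in bp, with :data:`MISSING` (0) for missing calls.  The pair is
    unordered; no phase is implied.
    """

    individuals: list[str]
    loci: list[LocusSpec]
    calls: np.ndarray
    populations: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individuals), len(self.loci)
        if n < 1 or L < 1:
            raise ValueError("need >= 1 individual and >= 1 locus")
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if not self.populations:
            self.populations = ["pop1"] * n
        if len(self.populations) != n:
            raise ValueError("populations must match individuals")
        for j, locus in enumerate(self.loci):
            a = self.calls[:, j, :]
            obs = a[a != MISSING]
            if obs.size == 0:
                continue
            if obs.min() < locus.min_len or obs.max() > locus.max_len:
                raise ValueError(
                    f"{locus.name}: allele outside [{locus.min_len}, "
                    f"{locus.max_len}]"
                )
            if np.any((obs - locus.min_len) % locus.motif_bp != 0):
                raise ValueError(f"{locus.name}: allele off the size lattice")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_calls(self, j: int) -> np.ndarray:
        """Non-missing gene copies at locus ``j`` as a flat array of sizes."""
        a = self.calls[:, j, :].ravel()
        return a[a != MISSING]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and [l.name for l in self.loci] == [l.name for l in other.loci]
            and np.array_equal(np.sort(self.calls, axis=2),
                               np.sort(other.calls, axis=2))
        )


@dataclass
class AlleleFreqTable:
    """Per-locus allele counts and normalized frequencies."""

    locus_names: list[str]
    counts: list[dict[int, int]]      # allele size -> gene-copy count
    n_copies: list[int]               # non-missing gene copies per locus
    all_missing: list[bool]

    def freqs(self, j: int) -> dict[int, float]:
        n = self.n_copies[j]
        if n == 0:
            return {}
        return {a: c / n for a, c in self.counts[j].items()}


def allele_freqs(gm: GenotypeMatrix) -> AlleleFreqTable:
    """Tabulate per-locus allele counts over non-missing gene copies.

    Loci at which every call is missing are flagged and carry an empty
    count table (they are excluded from any frequency normalization).
    """
    counts, n_copies, missing = [], [], []
    for j, locus in enumerate(gm.loci):
        obs = gm.locus_calls(j)
        if obs.size == 0:
            logger.warning("locus %s: all calls missing", locus.name)
            counts.append({})
            n_copies.append(0)
            missing.append(True)
            continue
        vals, cnt = np.unique(obs, return_counts=True)
        counts.append({int(v): int(c) for v, c in zip(vals, cnt)})
        n_copies.append(int(obs.size))
        missing.append(False)
    return AlleleFreqTable(
        [l.name for l in gm.loci], counts, n_copies, missing
    )


@dataclass
class HaplotypeAlignment:
    """Equal-length nucleotide sequences with identifiers."""

    ids: list[str]
    seqs: list[str]

    _ALPHABET = set("ACGTN-")

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if not self.seqs:
            raise ValueError("empty alignment")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        for s in self.seqs:
            if len(s) != L:
                raise ValueError("sequences differ in length")
            if set(s) - self._ALPHABET:
                raise ValueError(f"invalid characters: {set(s) - self._ALPHABET}")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def as_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.seqs).encode(), dtype="S1"
        ).reshape(self.n_seqs, self.length)


def read_fasta(path) -> HaplotypeAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return HaplotypeAlignment([r.id for r in records],
                              [str(r.seq) for r in records])


def write_fasta(aln: HaplotypeAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------


class GenepopParseError(ValueError):
    pass


class GenepopDialectError(GenepopParseError):
    pass


class GenepopEncodingError(ValueError):
    pass


def read_genepop(path, loci: list[LocusSpec] | None = None) -> GenotypeMatrix:
    """Read a Genepop file (2- or 3-digit diploid coding).

    The coding width is auto-detected from the first genotype token and
    must be consistent throughout the file.  Multiple POP blocks are
    concatenated, with population labels ``pop1``, ``pop2``, ... retained.
    If ``loci`` is not given, per-locus size frames are inferred from the
    observed alleles (motif 1 bp).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    locus_names: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        row = lines[i].strip()
        if row:
            locus_names.extend(t.strip() for t in row.split(",") if t.strip())
        i += 1
    if i >= len(lines):
        raise GenepopParseError("no POP separator found")
    if not locus_names:
        raise GenepopParseError("no locus names before first POP")
    L = len(locus_names)

    individuals, pops, rows = [], [], []
    width: int | None = None
    pop_idx = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," in line:
            name, _, rest = line.partition(",")
        else:
            raise GenepopParseError(
                f"line {lineno + 1}: missing ',' between id and genotypes"
            )
        toks = rest.split()
        if len(toks) != L:
            raise GenepopParseError(
                f"line {lineno + 1}: expected {L} genotypes, got {len(toks)}"
            )
        pair_row = np.empty((L, 2), dtype=np.int32)
        for j, tok in enumerate(toks):
            if not tok.isdigit() or len(tok) % 2 != 0:
                raise GenepopDialectError(
                    f"line {lineno + 1}: malformed genotype {tok!r}"
                )
            w = len(tok) // 2
            if w not in (2, 3):
                raise GenepopDialectError(
                    f"line {lineno + 1}: unsupported coding width {w}"
                )
            if width is None:
                width = w
            elif w != width:
                raise GenepopDialectError(
                    f"line {lineno + 1}: inconsistent coding width "
                    f"({w} vs {width})"
                )
            pair_row[j, 0] = int(tok[:w])
            pair_row[j, 1] = int(tok[w:])
        individuals.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(pair_row)

    if not rows:
        raise GenepopParseError("no individuals found")
    calls = np.stack(rows)

    if loci is None:
        loci = []
        for j, nm in enumerate(locus_names):
            obs = calls[:, j, :]
            obs = obs[obs != MISSING]
            lo = int(obs.min()) if obs.size else 1
            hi = int(obs.max()) if obs.size else 2
            if hi == lo:
                hi = lo + 1
            loci.append(LocusSpec(nm, motif_bp=1, min_len=lo, max_len=hi,
                                  mu=0.0, p_gsm=0.0))
    elif len(loci) != L:
        raise GenepopParseError(
            f"{L} loci in file but {len(loci)} LocusSpec given"
        )
    return GenotypeMatrix(individuals, list(loci), calls, pops)


def write_genepop(gm: GenotypeMatrix, path, title: str = "msatpop export",
                  width: int = 3) -> None:
    """Write a Genepop file; missing calls become all-zero codes."""
    if width not in (2, 3):
        raise GenepopEncodingError(f"unsupported coding width {width}")
    top = 10 ** width - 1
    if gm.calls.max() > top:
        raise GenepopEncodingError(
            f"allele size {gm.calls.max()} does not fit {width}-digit coding"
        )
    lines = [title]
    lines.extend(l.name for l in gm.loci)
    prev_pop = None
    for i, (ind, pop) in enumerate(zip(gm.individuals, gm.populations)):
        if pop != prev_pop:
            lines.append("POP")
            prev_pop = pop
        toks = [
            f"{gm.calls[i, j, 0]:0{width}d}{gm.calls[i, j, 1]:0{width}d}"
            for j in range(gm.n_loci)
        ]
        lines.append(f"{ind} , " + " ".join(toks))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
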