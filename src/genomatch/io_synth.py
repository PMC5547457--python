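"""Minimal VCF reading, synthetic database generation, golden fixture.

The parser reads only the CHROM/POS/REF/ALT columns of VCF 4.x text;
header lines are skipped and all other columns ignored.  The synthetic
generator emulates a germline variant database: records with distinct
(chromosome, position) tags across the 24 human chromosomes, positions up
to ~3e8, REF/ALT sequences over {A,T,G,C} of bounded length with mostly
single-nucleotide variants, and an unknown-allele ('.') fraction on
either side.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
import numpy as np

from .encoding import FormatError, VariantRecord

__all__ = [
    "SynthConfig",
    "parse_vcf",
    "write_vcf",
    "generate_synthetic",
    "table1_fixture",
]

_CHROM_LABELS = [str(i) for i in range(1, 23)] + ["X", "Y"]
_BASES = np.array(list("ATGC"))


def parse_vcf(path) -> list[VariantRecord]:
    """Read CHROM/POS/REF/ALT from a VCF 4.x text file.

    ``##`` meta lines and the ``#CHROM`` header are skipped.  Multi-allelic
    ALT fields (comma-separated) are rejected; '.' means unknown.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                fields = line.split()
            if len(fields) < 5:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 5 VCF columns"
                )
            chrom, pos, _id, ref, alt = fields[:5]
            if "," in alt or "," in ref:
                raise FormatError(
                    f"{path}:{lineno}: multi-allelic records are not supported"
                )
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad POS {pos!r}") from exc
            records.append(
                VariantRecord(chrom=chrom, pos=pos_i, ref=ref, alt=alt)
            )
    return records


def write_vcf(records, path) -> None:
    """Write records as minimal VCF 4.2 text (ID/QUAL/FILTER/INFO are '.')."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n"
            )


@dataclass(frozen=True)
class SynthConfig:
    """Shape of a synthetic variant database.

    ``unknown_prob`` is the chance that one side (REF or ALT) is the
    unknown string '.'; ``snv_prob`` is the chance that a known allele is
    a single base, otherwise its length is uniform in [2, n_snp].
    """

    n_records: int
    n_snp: int = 10
    unknown_prob: float = 0.1
    snv_prob: float = 0.8
    pos_max: int = 300_000_000
    seed: int = 0


def _draw_allele(rng: np.random.Generator, cfg: SynthConfig,
                 allow_unknown: bool = True) -> str:
    if allow_unknown and rng.random() < cfg.unknown_prob:
        return "."
    if rng.random() < cfg.snv_prob or cfg.n_snp < 2:
        length = 1
    else:
        length = int(rng.integers(2, cfg.n_snp + 1))
    return "".join(rng.choice(_BASES, size=length))


def generate_synthetic(config: SynthConfig) -> list[VariantRecord]:
    """Deterministically generate records with unique (chrom, pos) tags."""
    rng = np.random.default_rng(config.seed)
    seen = set()
    records = []
    while len(records) < config.n_records:
        chrom = _CHROM_LABELS[int(rng.integers(0, 24))]
        pos = int(rng.integers(1, config.pos_max + 1))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref = _draw_allele(rng, config)
        # at least one side must be a known sequence
        alt = _draw_allele(rng, config, allow_unknown=(ref != "."))
        records.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt))
    return records


def table1_fixture() -> list[tuple[VariantRecord, int, int]]:
    """The 17-row golden fixture of published (record, d, alpha) triples."""
    path = importlib.resources.files("genomatch") / "fixtures" / "table1.tsv"
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("CHROM"):
            continue
        chrom, pos, d, ref, alt, alpha = line.split("\t")
        rows.append(
            (VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt),
             int(d), int(alpha))
        )
    return rows
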