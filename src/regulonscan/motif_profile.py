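"""Binding-site profile with background-normalized column information.

Given n aligned l-bp sites, column i gets pseudocounted frequencies
p(i,b) = (counts(i,b)+1)/(n+4) and a relative-entropy weight

    I_hat_i = sum_b p(i,b) ln(p(i,b)/q(b))        (nats)

normalized by its analytic upper bound a — attained by a homogeneous
column of the rarest background base q0 = min_b q(b):

    a = (n+1)/(n+4) ln(n+1) - ln(n+4)
        - 1/(n+4) sum_b ln q(b) - n/(n+4) ln q0

so that I_i = I_hat_i / a lies in [0, 1].  Natural logs throughout; all
scores downstream are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from ._alphabet import BASES, encode
from .sequence_model import BackgroundModel, InputError

_IUPAC2 = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


@dataclass(frozen=True)
class SiteInstance:
    sequence: str
    source_genome: str | None = None
    source_tu: str | None = None
    name: str | None = None
    offset: int | None = None

    def __post_init__(self):
        if any(c not in BASES for c in self.sequence):
            raise InputError(f"site {self.name or self.sequence} contains ambiguous bases")


@dataclass
class MotifProfile:
    length: int  # l
    n_sites: int  # n
    counts: np.ndarray  # (l, 4) integer counts
    p: np.ndarray  # (l, 4) pseudocounted frequencies
    background: BackgroundModel  # q used at build time
    information: np.ndarray = field(init=False)  # I_i, unitless, in [0, 1]
    bound: float = field(init=False)  # a, nats

    def __post_init__(self):
        q = self.background.q
        n = self.n_sites
        q0 = float(q.min())
        self.bound = (
            (n + 1) / (n + 4) * math.log(n + 1)
            - math.log(n + 4)
            - float(np.log(q).sum()) / (n + 4)
            - n / (n + 4) * math.log(q0)
        )
        pre = np.sum(self.p * np.log(self.p / q[None, :]), axis=1)
        self.information = pre / self.bound


def information_bound(n: int, q: np.ndarray) -> float:
    """Upper bound a of a column's relative entropy (see module docstring)."""
    q = np.asarray(q, dtype=float)
    q0 = float(q.min())
    return (
        (n + 1) / (n + 4) * math.log(n + 1)
        - math.log(n + 4)
        - float(np.log(q).sum()) / (n + 4)
        - n / (n + 4) * math.log(q0)
    )


def build_profile(
    sites: Sequence[SiteInstance | str], background: BackgroundModel
) -> MotifProfile:
    """Build the scanning profile from equal-length ungapped sites."""
    seqs = [s.sequence if isinstance(s, SiteInstance) else s for s in sites]
    if not seqs:
        raise InputError("build_profile: no sites supplied")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise InputError("build_profile: sites have unequal lengths")
    counts = np.zeros((length, 4), dtype=np.int64)
    for s in seqs:
        codes = encode(s)
        if (codes > 3).any():
            raise InputError(f"site {s!r} contains ambiguous bases")
        counts[np.arange(length), codes] += 1
    n = len(seqs)
    p = (counts + 1.0) / (n + 4.0)
    return MotifProfile(length=length, n_sites=n, counts=counts, p=p, background=background)


def consensus(profile: MotifProfile, major_frac: float = 0.5, pair_frac: float = 0.75) -> str:
    """Degenerate IUPAC consensus from raw (un-pseudocounted) frequencies.

    Per column: the single base with raw frequency >= ``major_frac``;
    otherwise the two-base IUPAC code when the top two bases jointly reach
    ``pair_frac``; otherwise N.
    """
    out = []
    n = profile.n_sites
    for i in range(profile.length):
        freq = profile.counts[i] / n
        order = np.argsort(-freq, kind="stable")
        if freq[order[0]] >= major_frac:
            out.append(BASES[order[0]])
        elif freq[order[0]] + freq[order[1]] >= pair_frac:
            pair = frozenset((BASES[order[0]], BASES[order[1]]))
            out.append(_IUPAC2[pair])
        else:
            out.append("N")
    return "".join(out)


# ---------------------------------------------------------------------------
# site list I/O


def load_sites_tsv(path: str | Path) -> list[SiteInstance]:
    """Read a site list TSV with columns genome, tu, name, sequence, position."""
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            sites.append(
                SiteInstance(
                    sequence=row[col["sequence"]],
                    source_genome=row[col["genome"]] if "genome" in col else None,
                    source_tu=row[col["tu"]] if "tu" in col else None,
                    name=row[col["name"]] if "name" in col else None,
                    offset=int(row[col["position"]]) if "position" in col else None,
                )
            )
    return sites


def load_sites_fasta(path: str | Path) -> list[SiteInstance]:
    return [
        SiteInstance(sequence=str(rec.seq).upper(), name=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def load_reference_sites() -> list[SiteInstance]:
    """The packaged list of 48 14-bp cyanobacterial LexA boxes.

    These are the phylogenetic-footprinting sites used to build the
    scanning profile (one additional candidate site was excluded upstream
    of this list for lack of experimental support, leaving 48).
    """
    ref = resources.files("regulonscan").joinpath("data/table1_sites.tsv")
    with resources.as_file(ref) as path:
        return load_sites_tsv(path)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme_motif(
    profile: MotifProfile, path: str | Path, name: str = "motif1"
) -> None:
    """Write the profile as a MEME minimal motif file (letter-probability
    matrix over the build-time background)."""
    q = profile.background.q
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {q[0]:.6f} C {q[1]:.6f} G {q[2]:.6f} T {q[3]:.6f}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {profile.length} "
            f"nsites= {profile.n_sites} E= 0\n"
        )
        for row in profile.p:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_meme_motif(path: str | Path) -> tuple[np.ndarray, int, np.ndarray]:
    """Read back a minimal MEME motif: (probability matrix, nsites, background)."""
    p_rows: list[list[float]] = []
    nsites = 0
    width = 0
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            background = np.array([float(toks[j]) for j in (1, 3, 5, 7)])
        if line.startswith("letter-probability matrix"):
            toks = line.replace("=", " = ").split()
            width = int(toks[toks.index("w") + 2])
            nsites = int(toks[toks.index("nsites") + 2])
            for row_line in lines[i + 1 : i + 1 + width]:
                p_rows.append([float(v) for v in row_line.split()])
            break
    if not p_rows:
        raise InputError(f"{path}: no letter-probability matrix found")
    return np.array(p_rows), nsites, background
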