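"""Sequence input and charge bookkeeping for polyampholyte analysis.

A disordered polyanion such as the coral aspartic/glutamic acid-rich protein
(AGARP, 506 residues, net side-chain charge near -148 e at pH 8) is
characterised here only through its charge composition: the fractions ``f``
and ``g`` of positively and negatively charged residues, the net charge and
linear charge density, and the positions of condensed-charge motifs (maximal
runs of D/E residues), which are candidate chelation sites for divalent
cations.

Two charge schemes are supported:

``binary``
    D/E -> -1, K/R -> +1, everything else (including His) neutral.  This is
    the convention consumed by the polymer theory (fractions ``f`` and ``g``).
``hps``
    The coarse-grained simulation convention: Arg/Lys +1, Asp/Glu -1,
    His +0.5, all other residues 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Side-chain charges (units of e) per scheme.
CHARGE_SCHEMES: dict[str, dict[str, float]] = {
    "binary": {"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0},
    "hps": {"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0, "H": +0.5},
}


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a non-standard one-letter code."""

    def __init__(self, code: str, position: int):
        self.code = code
        self.position = position  # 1-based
        super().__init__(
            f"unknown residue code {code!r} at position {position} "
            "(only the 20 standard one-letter codes are accepted)"
        )


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Parameters
    ----------
    identifier:
        Free-text record id.
    residues:
        One-letter codes, upper-case, standard 20 only.
    """

    identifier: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        object.__setattr__(self, "residues", self.residues.upper())
        for i, aa in enumerate(self.residues, start=1):
            if aa not in STANDARD_AA:
                raise UnknownResidueError(aa, i)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass(frozen=True)
class ChargeProfile:
    """Charge composition of a sequence under a fixed charge scheme."""

    scheme: str
    per_residue_charge: tuple[float, ...]
    n_pos: int
    n_neg: int
    f: float
    g: float
    net_charge: float
    charge_density: float
    include_termini: bool = False

    @property
    def n(self) -> int:
        return len(self.per_residue_charge)

    @property
    def n_neutral(self) -> int:
        return self.n - self.n_pos - self.n_neg


def charge_profile(
    seq: ProteinSequence | str,
    scheme: str = "binary",
    include_termini: bool = False,
) -> ChargeProfile:
    """Compute per-residue charges, counts, fractions and net charge.

    ``f`` and ``g`` are the fractions of residues carrying positive and
    negative side-chain charge; termini, when enabled, add +1/-1 e to the net
    charge but are never counted in ``f``/``g`` (they are not residues).

    Parameters
    ----------
    seq:
        Sequence or raw residue string.
    scheme:
        ``"binary"`` or ``"hps"`` (see module docstring).
    include_termini:
        Add an N-terminal +1 e and a C-terminal -1 e to the net charge.
    """
    if isinstance(seq, str):
        seq = ProteinSequence("anonymous", seq)
    try:
        charges = CHARGE_SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; choose from {sorted(CHARGE_SCHEMES)}"
        ) from None
    per_res = tuple(charges.get(aa, 0.0) for aa in seq)
    n = len(per_res)
    n_pos = sum(1 for q in per_res if q > 0)
    n_neg = sum(1 for q in per_res if q < 0)
    net = sum(per_res)
    if include_termini:
        net += 1.0 - 1.0  # NH3+ and COO-; cancels, kept explicit
    return ChargeProfile(
        scheme=scheme,
        per_residue_charge=per_res,
        n_pos=n_pos,
        n_neg=n_neg,
        f=n_pos / n,
        g=n_neg / n,
        net_charge=net,
        charge_density=net / n,
        include_termini=include_termini,
    )


def charge_density(net_charge: float, n_residues: int) -> float:
    """Linear charge density in e per residue: ``net_charge / N``."""
    if n_residues < 1:
        raise ValueError("N must be >= 1")
    return net_charge / n_residues


def acidic_motif_scan(
    seq: ProteinSequence | str, min_run: int = 2
) -> list[tuple[int, int, int]]:
    """Locate maximal runs of acidic residues (D/E).

    Returns ``(start, end, length)`` triples, 1-based inclusive, sorted by
    start.  Only maximal runs are reported: the residues flanking each run
    are guaranteed not to be D or E.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if isinstance(seq, str):
        seq = ProteinSequence("anonymous", seq)
    runs: list[tuple[int, int, int]] = []
    start = None
    for i, aa in enumerate(seq.residues + "X", start=1):  # sentinel flush
        if aa in "DE":
            if start is None:
                start = i
        elif start is not None:
            length = i - start
            if length >= min_run:
                runs.append((start, i - 1, length))
            start = None
    return runs


def run_length_histogram(
    seq: ProteinSequence | str, min_run: int = 1
) -> dict[int, int]:
    """Histogram of acidic-run lengths (length -> count)."""
    hist: dict[int, int] = {}
    for _, _, length in acidic_motif_scan(seq, min_run=min_run):
        hist[length] = hist.get(length, 0) + 1
    return dict(sorted(hist.items()))


def read_fasta(path: str | Path, record_id: str | None = None) -> ProteinSequence:
    """Read one record from a (multi-)FASTA file.

    The first record is used unless ``record_id`` names another one.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise KeyError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return ProteinSequence(rec.id, str(rec.seq))


def write_charge_track(
    profile: ChargeProfile, seq: ProteinSequence, path: str | Path
) -> None:
    """Write a per-residue charge track as CSV (position, residue, charge)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position", "residue", "charge_e"])
        for i, (aa, q) in enumerate(zip(seq, profile.per_residue_charge), start=1):
            writer.writerow([i, aa, q])
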