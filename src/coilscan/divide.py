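"""Divide a full-length protein sequence into overlapping fragment queries.

A fragmentation *specification* is a string ``N_L_O``: the sequence is cut
into windows of ``L`` residues advancing by ``L - O`` (so consecutive windows
share ``O`` residues), and each window is emitted as a homo-oligomeric
prediction query of ``N`` identical chains.  If the last regular window would
run past the C-terminus, the window length takes priority: the final window
is anchored at the C-terminus and its overlap with the previous window grows
accordingly.  An optional flank sequence (a short well-folding coiled-coil
adaptor) can be attached to both termini of every window to promote folding;
it is stripped again before feature integration.

The on-disk product of a division is a *run directory* containing
``parameters.json`` (everything needed to reproduce the run), a
``constructs.csv`` table (one row per fragment) and a ``queries/`` folder of
FASTA files ready to submit to a structure-prediction server.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SequenceError, SpecError

#: canonical amino acids plus X (unknown)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_SPEC_RE = re.compile(r"^(\d+)_(\d+)_(\d+)$")


@dataclass(frozen=True)
class FragmentSpec:
    """An ``N_L_O`` fragmentation recipe.

    Attributes
    ----------
    n_copies : int
        Oligomeric state N: number of identical chains per query.
    window_length : int
        Window length L in residues.
    overlap : int
        Overlap O between consecutive windows, ``0 <= O <= L - 1``.
    flank : str
        Sequence attached to both termini of every window (may be empty).
    """

    n_copies: int
    window_length: int
    overlap: int
    flank: str = ""

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise SpecError(f"oligomeric state must be >= 1, got {self.n_copies}")
        if self.window_length < 1:
            raise SpecError(f"window length must be >= 1, got {self.window_length}")
        if not 0 <= self.overlap <= self.window_length - 1:
            raise SpecError(
                f"overlap must satisfy 0 <= O <= L-1 = {self.window_length - 1}, "
                f"got {self.overlap}"
            )
        bad = sorted(set(self.flank) - AMINO_ACIDS)
        if bad:
            raise SequenceError(f"flank contains non-amino-acid characters: {bad}")

    @property
    def label(self) -> str:
        """Canonical ``N_L_O`` string."""
        return f"{self.n_copies}_{self.window_length}_{self.overlap}"

    @property
    def step(self) -> int:
        return self.window_length - self.overlap

    @classmethod
    def parse(cls, label: str, flank: str = "") -> "FragmentSpec":
        """Parse an ``N_L_O`` label, e.g. ``"2_30_15"`` -> dimer, L=30, O=15."""
        m = _SPEC_RE.match(label.strip())
        if m is None:
            raise SpecError(
                f"malformed specification {label!r}: expected N_L_O with integer "
                "oligomer count, window length and overlap (e.g. 2_30_15)"
            )
        n, length, overlap = (int(g) for g in m.groups())
        return cls(n_copies=n, window_length=length, overlap=overlap, flank=flank)


def parse_spec(label: str, flank: str = "") -> FragmentSpec:
    """Functional alias for :meth:`FragmentSpec.parse`."""
    return FragmentSpec.parse(label, flank=flank)


@dataclass(frozen=True)
class FragmentWindow:
    """One window of the full-length sequence, 0-based half-open [start, end)."""

    fragment_index: int
    start: int
    end: int
    core_sequence: str
    query_sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(sequence_length: int, spec: FragmentSpec) -> list[tuple[int, int]]:
    """Tile ``[0, sequence_length)`` with windows of the spec's length.

    Starts advance by ``L - O``.  If the last regular window falls short of
    the C-terminus, a final window ``[sequence_length - L, sequence_length)``
    is appended: the window length takes priority and the last overlap grows.
    A sequence shorter than one window yields the single window covering it
    (with a warning) rather than an error, so short proteins remain scannable.
    """
    if sequence_length < 1:
        raise SequenceError(f"sequence length must be >= 1, got {sequence_length}")
    L = spec.window_length
    if sequence_length < L:
        warnings.warn(
            f"sequence length {sequence_length} < window length {L}; "
            "emitting a single full-sequence window",
            stacklevel=2,
        )
        return [(0, sequence_length)]
    windows = [(s, s + L) for s in range(0, sequence_length - L + 1, spec.step)]
    if windows[-1][1] < sequence_length:
        windows.append((sequence_length - L, sequence_length))
    return windows


def validate_sequence(sequence: str) -> str:
    """Check a protein sequence (canonical 20 letters + X); return it uppercased."""
    if not sequence:
        raise SequenceError("empty sequence")
    seq = sequence.upper()
    bad = [i for i, c in enumerate(seq) if c not in AMINO_ACIDS]
    if bad:
        shown = ", ".join(f"{seq[i]!r}@{i}" for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise SequenceError(f"non-amino-acid characters at positions: {shown}{more}")
    return seq


def _sanitize_id(seq_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9.-]", "_", seq_id) or "query"


def query_file_name(seq_id: str, spec_label: str, fragment_index: int) -> str:
    """Deterministic, sortable FASTA file name for one fragment query."""
    return f"{_sanitize_id(seq_id)}__{spec_label}__f{fragment_index:04d}.fasta"


@dataclass
class DivisionManifest:
    """Everything the integrator needs to map fragments back to the sequence."""

    sequence_id: str
    sequence: str
    specs: list[FragmentSpec]
    windows: dict[str, list[FragmentWindow]] = field(default_factory=dict)
    flank: str = ""

    def query_file(self, spec_label: str, fragment_index: int) -> str:
        return query_file_name(self.sequence_id, spec_label, fragment_index)

    @property
    def sequence_length(self) -> int:
        return len(self.sequence)

    def constructs_frame(self) -> pd.DataFrame:
        """Construct table; start/end are 1-based inclusive for readability."""
        rows = []
        for spec in self.specs:
            for w in self.windows[spec.label]:
                rows.append(
                    {
                        "spec_label": spec.label,
                        "fragment_index": w.fragment_index,
                        "start_1based": w.start + 1,
                        "end_1based": w.end,
                        "core_length": w.length,
                        "flank_length": len(self.flank),
                        "query_file": self.query_file(spec.label, w.fragment_index),
                    }
                )
        return pd.DataFrame(rows)

    def parameters_dict(self) -> dict:
        from . import __version__

        return {
            "tool": "coilscan",
            "version": __version__,
            "sequence_id": self.sequence_id,
            "sequence": self.sequence,
            "specs": [s.label for s in self.specs],
            "flank": self.flank,
        }

    def write(self, outdir: str | Path, multimer_style: str = "colon") -> Path:
        """Write parameters.json, constructs.csv and queries/ under ``outdir``.

        ``multimer_style`` selects the homo-oligomer FASTA dialect:
        ``"colon"`` writes one record whose sequence is the chain repeated
        ``n_copies`` times joined by ':' (the common prediction-server
        dialect); ``"records"`` writes one record per chain copy.
        """
        if multimer_style not in ("colon", "records"):
            raise ValueError(f"unknown multimer style {multimer_style!r}")
        outdir = Path(outdir)
        qdir = outdir / "queries"
        qdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "parameters.json", "w") as fh:
            json.dump(self.parameters_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.constructs_frame().to_csv(outdir / "constructs.csv", index=False)
        for spec in self.specs:
            for w in self.windows[spec.label]:
                name = self.query_file(spec.label, w.fragment_index)
                header = name[: -len(".fasta")]
                with open(qdir / name, "w") as fh:
                    if multimer_style == "colon":
                        seq = ":".join([w.query_sequence] * spec.n_copies)
                        fh.write(f">{header}\n{seq}\n")
                    else:
                        for c in range(spec.n_copies):
                            fh.write(f">{header}_chain{c}\n{w.query_sequence}\n")
        return outdir

    @classmethod
    def read(cls, rundir: str | Path) -> "DivisionManifest":
        """Reconstruct a manifest from a run directory written by :meth:`write`."""
        rundir = Path(rundir)
        with open(rundir / "parameters.json") as fh:
            params = json.load(fh)
        flank = params.get("flank", "")
        specs = [FragmentSpec.parse(lbl, flank=flank) for lbl in params["specs"]]
        manifest = cls(
            sequence_id=params["sequence_id"],
            sequence=params["sequence"],
            specs=specs,
            flank=flank,
        )
        table = pd.read_csv(rundir / "constructs.csv")
        for spec in specs:
            sub = table[table["spec_label"] == spec.label].sort_values("fragment_index")
            wins = []
            for _, row in sub.iterrows():
                start = int(row["start_1based"]) - 1
                end = int(row["end_1based"])
                core = manifest.sequence[start:end]
                wins.append(
                    FragmentWindow(
                        fragment_index=int(row["fragment_index"]),
                        start=start,
                        end=end,
                        core_sequence=core,
                        query_sequence=flank + core + flank,
                    )
                )
            manifest.windows[spec.label] = wins
        return manifest


def build_queries(
    sequence: str,
    specs: Sequence[FragmentSpec | str],
    sequence_id: str = "query",
    flank: str = "",
) -> DivisionManifest:
    """Window ``sequence`` under every spec and assemble the division manifest.

    Specs given as strings are parsed; the ``flank`` argument overrides any
    flank carried by pre-built :class:`FragmentSpec` objects so that one run
    uses one flank consistently.
    """
    seq = validate_sequence(sequence)
    flank = validate_sequence(flank) if flank else ""
    parsed: list[FragmentSpec] = []
    for s in specs:
        spec = FragmentSpec.parse(s, flank=flank) if isinstance(s, str) else s
        if spec.flank != flank:
            spec = FragmentSpec(spec.n_copies, spec.window_length, spec.overlap, flank)
        parsed.append(spec)
    if len({s.label for s in parsed}) != len(parsed):
        raise SpecError("duplicate specification labels")
    manifest = DivisionManifest(
        sequence_id=sequence_id, sequence=seq, specs=parsed, flank=flank
    )
    for spec in parsed:
        wins = []
        for i, (start, end) in enumerate(make_windows(len(seq), spec)):
            core = seq[start:end]
            wins.append(
                FragmentWindow(
                    fragment_index=i,
                    start=start,
                    end=end,
                    core_sequence=core,
                    query_sequence=flank + core + flank,
                )
            )
        manifest.windows[spec.label] = wins
    return manifest


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; return (id, sequence)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise SequenceError(
            f"expected a single FASTA record in {path}, found {len(records)}"
        )
    return records[0].id, str(records[0].seq)
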