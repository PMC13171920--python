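"""Exhaustive sliding-window MHC class II epitope scan.

Every linear k-mer (default 15, the optimal length for HLA-II binding
grooves) of a protein is enumerated with stride 1 — a protein of length N
yields N - k + 1 windows — and scored against one HLA-II allele with a
pluggable binding-affinity backend returning a predicted IC50 in nM.  The
predicted best binding affinity (PBBA) of the protein/allele pair is the
minimum IC50 over all windows, and windows with IC50 below a threshold
(default 50 nM) are reported as strong-binder "hits".

Trained neural-network predictors (e.g. the IEDB NetMHCpan BA tool) are
deliberately not re-implemented: the backend protocol accepts any callable
object, a reader for precomputed per-peptide score tables is provided, and a
deterministic mock backend makes the scan logic fully testable offline.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Protocol, runtime_checkable

import pandas as pd

__all__ = [
    "ProteinRecord",
    "Window",
    "ScoredWindow",
    "EpitopeScanResult",
    "AffinityBackend",
    "MockAffinityBackend",
    "TableAffinityBackend",
    "read_fasta",
    "enumerate_windows",
    "score_windows",
    "summarize_scan",
    "scan_protein",
    "HIT_THRESHOLD_NM",
    "WINDOW_SIZE",
]

WINDOW_SIZE = 15
HIT_THRESHOLD_NM = 50.0

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS_AA = set("XBZJUO")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _STANDARD_AA - _AMBIGUOUS_AA
        if bad:
            raise ValueError(f"sequence of {self.id!r} contains invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return bool(set(self.sequence) & _AMBIGUOUS_AA)


class Window(NamedTuple):
    """One k-mer window; ``start`` is the 1-based inclusive position."""

    start: int
    peptide: str


class ScoredWindow(NamedTuple):
    start: int
    peptide: str
    ic50_nM: float


@runtime_checkable
class AffinityBackend(Protocol):
    """Maps (peptide, allele) to a predicted IC50 in nM (> 0)."""

    def predict_ic50(self, peptide: str, allele: str) -> float: ...


class MockAffinityBackend:
    """Deterministic stand-in predictor for offline testing.

    IC50 values are log-uniform on [1, 50000] nM, derived from a stable hash
    of (peptide, allele, seed): the same peptide/allele pair always scores
    identically, across processes and runs.  ``planted`` pins chosen peptides
    to exact values, e.g. to construct a known minimum.
    """

    def __init__(self, seed: int = 0, planted: dict[str, float] | None = None):
        self.seed = int(seed)
        self.planted = dict(planted or {})

    def predict_ic50(self, peptide: str, allele: str) -> float:
        if peptide in self.planted:
            return float(self.planted[peptide])
        digest = hashlib.blake2b(
            f"{self.seed}|{allele}|{peptide}".encode(), digest_size=8
        ).digest()
        u = int.from_bytes(digest, "big") / 2**64  # uniform [0, 1)
        return float(10.0 ** (u * math.log10(50000.0)))  # log-uniform [1, 50000] nM


class TableAffinityBackend:
    """Backend backed by a precomputed per-peptide score table.

    The table format is TSV with columns ``peptide``, ``allele``,
    ``ic50_nM`` — the natural shape of an external predictor's tabular
    export.  Unknown peptides raise ``KeyError`` (the scan flags and
    excludes them).
    """

    def __init__(self, scores: pd.DataFrame):
        required = {"peptide", "allele", "ic50_nM"}
        if not required.issubset(scores.columns):
            raise ValueError(f"score table needs columns {sorted(required)}")
        self._scores = {
            (str(r.peptide).upper(), str(r.allele)): float(r.ic50_nM)
            for r in scores.itertuples()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableAffinityBackend":
        return cls(pd.read_csv(path, sep="\t"))

    def predict_ic50(self, peptide: str, allele: str) -> float:
        try:
            return self._scores[(peptide.upper(), allele)]
        except KeyError:
            raise KeyError(f"no precomputed score for peptide {peptide!r}, allele {allele!r}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file."""
    from Bio import SeqIO

    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def enumerate_windows(protein: ProteinRecord | str, k: int = WINDOW_SIZE) -> list[Window]:
    """All k-mer windows of the protein at stride 1, in sequence order.

    A protein of length N yields exactly N - k + 1 windows with 1-based
    start positions 1..N-k+1.  A sequence shorter than k is an error.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else str(protein).upper()
    if k < 1:
        raise ValueError("window size must be at least 1")
    n = len(seq)
    if n < k:
        raise ValueError(f"sequence length {n} is shorter than the window size {k}")
    return [Window(start=i + 1, peptide=seq[i : i + k]) for i in range(n - k + 1)]


def score_windows(
    windows: Iterable[Window],
    allele: str,
    backend: AffinityBackend,
    cache: dict | None = None,
) -> tuple[list[ScoredWindow], list[Window]]:
    """Score every window against one allele.

    Backend calls are cached by (peptide, allele), so duplicate peptides are
    scored once and identically.  A backend failure on a peptide flags the
    window as failed (returned separately, excluded from any summary) with a
    warning instead of aborting the scan.
    """
    cache = {} if cache is None else cache
    scored: list[ScoredWindow] = []
    failed: list[Window] = []
    for w in windows:
        key = (w.peptide, allele)
        if key not in cache:
            try:
                ic50 = float(backend.predict_ic50(w.peptide, allele))
                if not (ic50 > 0) or not math.isfinite(ic50):
                    raise ValueError(f"backend returned non-positive IC50 {ic50!r}")
                cache[key] = ic50
            except Exception as exc:
                warnings.warn(f"window at {w.start} ({w.peptide}) failed scoring: {exc}")
                cache[key] = None
        ic50 = cache[key]
        if ic50 is None:
            failed.append(w)
        else:
            scored.append(ScoredWindow(start=w.start, peptide=w.peptide, ic50_nM=ic50))
    return scored, failed


@dataclass
class EpitopeScanResult:
    """Scan summary for one protein x one HLA-II allele."""

    protein_id: str
    allele: str
    window_size: int
    windows: list[ScoredWindow]
    pbba: float  # predicted best binding affinity = min IC50, nM
    hits: list[ScoredWindow]  # IC50 < threshold, ascending by IC50
    threshold: float
    failed_windows: list[Window] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    def to_frame(self) -> pd.DataFrame:
        """Per-window table with 1-based start positions."""
        return pd.DataFrame(
            {
                "allele": self.allele,
                "protein_id": self.protein_id,
                "start": [w.start for w in self.windows],
                "peptide": [w.peptide for w in self.windows],
                "ic50_nM": [w.ic50_nM for w in self.windows],
                "hit": [w.ic50_nM < self.threshold for w in self.windows],
            }
        )

    def summary(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "allele": self.allele,
            "pbba_nM": round(self.pbba, 1),
            "n_windows": self.n_windows,
            "n_hits": self.n_hits,
            "threshold_nM": self.threshold,
            "n_failed_windows": len(self.failed_windows),
        }


def summarize_scan(
    scored: list[ScoredWindow],
    threshold: float = HIT_THRESHOLD_NM,
    protein_id: str = "",
    allele: str = "",
    window_size: int = WINDOW_SIZE,
    failed: list[Window] | None = None,
) -> EpitopeScanResult:
    """Reduce scored windows to PBBA and the strong-binder hit list.

    PBBA is the minimum IC50 over all successfully scored windows (smaller
    IC50 = stronger predicted binding); hits are windows with IC50 strictly
    below the threshold, sorted ascending by IC50.
    """
    if not scored:
        raise ValueError("no successfully scored windows to summarize")
    pbba = min(w.ic50_nM for w in scored)
    hits = sorted((w for w in scored if w.ic50_nM < threshold), key=lambda w: w.ic50_nM)
    return EpitopeScanResult(
        protein_id=protein_id,
        allele=allele,
        window_size=window_size,
        windows=list(scored),
        pbba=pbba,
        hits=hits,
        threshold=threshold,
        failed_windows=list(failed or []),
    )


def scan_protein(
    protein: ProteinRecord,
    allele: str,
    backend: AffinityBackend,
    k: int = WINDOW_SIZE,
    threshold: float = HIT_THRESHOLD_NM,
) -> EpitopeScanResult:
    """Enumerate, score and summarize in one call."""
    windows = enumerate_windows(protein, k=k)
    scored, failed = score_windows(windows, allele, backend)
    return summarize_scan(
        scored,
        threshold=threshold,
        protein_id=protein.id,
        allele=allele,
        window_size=k,
        failed=failed,
    )
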