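"""Junction-spanning peptide enumeration and MHC-binding thresholding.

Variant transcripts are translated from their annotated start codon;
candidate peptides are all 8-11mer (configurable) windows containing coding
sequence from both sides of the novel junction.  Candidates occurring
anywhere in the reference peptidome — the set of proteins translated from
annotated coding transcripts — are removed; survivors are scored against
each HLA allele by a pluggable affinity predictor, and a peptide is a
predicted neoantigen when its affinity is strictly below the binder
threshold (500 nM by default).
"""

from __future__ import annotations

import hashlib
import logging
import re
import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, Optional, Protocol, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .config import PipelineConfig
from .io import Annotation, Genome
from .transcripts import VariantTranscript

log = logging.getLogger(__name__)

_CODON = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_ALLELE_RE = re.compile(r"^HLA-[A-Z]{1,3}\d*\*\d+:\d+$")


def translate_cds(nt: str, frame: int = 0) -> str:
    """Translate under the standard genetic code.

    Translation stops before the first stop codon; a trailing partial codon
    is dropped; a codon containing a non-ACGT base yields no residue and
    truncates the product there.  A sequence shorter than frame + 3 gives "".
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    nt = nt.upper()
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in _STOPS:
            break
        aa = _CODON.get(codon)
        if aa is None:
            break
        out.append(aa)
    return "".join(out)


@dataclass
class PeptideCandidate:
    sequence: str
    junction_id: str
    transcript_id: str
    residue_start: int  # 0-based window start within the translated protein
    spans_junction: bool = True
    in_reference_peptidome: Optional[bool] = None

    def __len__(self) -> int:
        return len(self.sequence)


def enumerate_junction_peptides(
    vt: VariantTranscript, cfg: PipelineConfig
) -> list[PeptideCandidate]:
    """All peptide windows spanning the novel junction of ``vt``.

    A window spans the junction when it contains at least one residue whose
    codon includes a base strictly upstream of the junction and one whose
    codon includes a base at or after it; a codon split by the junction
    satisfies both sides by itself.  Windows are truncated by stop codons
    through translation, so a stop upstream of the junction yields nothing.
    """
    protein = translate_cds(vt.sequence, 0)
    if not protein:
        return []
    j = vt.junction_offset
    if j <= 0:
        return []
    split = j % 3 != 0
    last_up = (j - 1) // 3        # residue with the last strictly-upstream base
    first_down = j // 3 if not split else last_up
    out: list[PeptideCandidate] = []
    for L in sorted(cfg.peptide_lengths):
        for w in range(0, len(protein) - L + 1):
            hi = w + L - 1
            if split:
                spans = w <= last_up <= hi
            else:
                spans = w <= last_up and hi >= first_down
            if spans:
                out.append(
                    PeptideCandidate(
                        sequence=protein[w : w + L],
                        junction_id=vt.junction.junction_id,
                        transcript_id=vt.anchor_transcript_id,
                        residue_start=w,
                    )
                )
    return out


class Peptidome:
    """Reference proteins supporting exact substring membership queries."""

    def __init__(self, proteins: Iterable[str]):
        self.proteins = sorted(set(proteins))
        self._haystack = "#" + "#".join(self.proteins) + "#"

    def __contains__(self, query: str) -> bool:
        if not query or "#" in query:
            return False
        return query in self._haystack

    def __len__(self) -> int:
        return len(self.proteins)


def build_reference_peptidome(annotation: Annotation, genome: Genome) -> Peptidome:
    """Translate every annotated coding transcript into the peptidome.

    Each CDS is spliced, strand-adjusted and translated (stop-truncated);
    a CDS whose length is not a multiple of 3 after phase adjustment is
    translated over its readable prefix with a warning.
    """
    proteins = []
    for t in annotation.transcripts():
        if not t.is_coding:
            continue
        cds = t.cds_sequence(genome)
        phase = 0
        if t.cds_phases:
            phase = t.cds_phases[0] if t.strand == "+" else t.cds_phases[-1]
            # GENCODE phase: bases to skip before the first complete codon
            order = t.cds_phases if t.strand == "+" else t.cds_phases[::-1]
            phase = order[0]
        if (len(cds) - phase) % 3 != 0:
            log.warning(
                "transcript %s: CDS length %d (phase %d) not a codon "
                "multiple; translating readable prefix",
                t.transcript_id, len(cds), phase,
            )
        proteins.append(translate_cds(cds, phase))
    return Peptidome(p for p in proteins if p)


def filter_peptides(
    candidates: Iterable[PeptideCandidate], peptidome: Peptidome
) -> list[PeptideCandidate]:
    """Remove reference-peptidome hits; deduplicate by (sequence, junction)."""
    out: list[PeptideCandidate] = []
    seen: set[tuple[str, str]] = set()
    for c in candidates:
        c.in_reference_peptidome = c.sequence in peptidome
        if c.in_reference_peptidome:
            continue
        key = (c.sequence, c.junction_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Binding prediction
# ---------------------------------------------------------------------------


@dataclass
class BindingCall:
    peptide: PeptideCandidate
    allele: str
    affinity_nM: float
    is_binder: bool


class AffinityPredictor(Protocol):
    def predict(self, peptides: Sequence[str], allele: str) -> list[float]: ...


class StubPredictor:
    """Deterministic hash-based affinity oracle in [1, 50000] nM.

    Affinities derive from a fixed-key SHA-256 of (allele, peptide), so runs
    are reproducible everywhere without an external binary.  The stub has no
    immunological meaning; it exists so the full pipeline, including the
    strict <500 nM binder rule, is exercisable hermetically.
    """

    def __init__(self, key: str = "splicigen-stub-v1"):
        self.key = key

    def predict(self, peptides: Sequence[str], allele: str) -> list[float]:
        out = []
        for p in peptides:
            h = hashlib.sha256(f"{self.key}|{allele}|{p}".encode()).digest()
            v = int.from_bytes(h[:8], "big")
            out.append(1.0 + (v % 4_999_900) / 100.0)  # 1.00 .. 50000.00
        return out


class NetMHCpanPredictor:
    """Adapter around an installed netMHCpan-style binary.

    Invokes ``<tool> -BA -p <pepfile> -a <allele>`` and parses the tabular
    output's peptide and Aff(nM) columns.  Raises a RuntimeError naming the
    tool when it is missing or exits nonzero.
    """

    def __init__(self, path: str = "netMHCpan"):
        self.path = path

    def predict(self, peptides: Sequence[str], allele: str) -> list[float]:
        import tempfile

        if shutil.which(self.path) is None:
            raise RuntimeError(f"binding predictor {self.path!r} not found on PATH")
        with tempfile.NamedTemporaryFile("w", suffix=".pep", delete=False) as fh:
            fh.write("\n".join(peptides) + "\n")
            pepfile = fh.name
        proc = subprocess.run(
            [self.path, "-BA", "-p", pepfile, "-a", allele.replace("*", "")],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"{self.path} exited {proc.returncode}: {proc.stderr.strip()[:500]}"
            )
        aff: dict[str, float] = {}
        for line in proc.stdout.splitlines():
            parts = line.split()
            for i, tok in enumerate(parts):
                if tok in peptides and i + 1 < len(parts):
                    for cand in parts[i + 1 :]:
                        try:
                            val = float(cand)
                        except ValueError:
                            continue
                        aff[tok] = val  # last numeric column = Aff(nM)
        missing = [p for p in peptides if p not in aff]
        if missing:
            raise RuntimeError(
                f"{self.path}: no affinity parsed for {len(missing)} peptides"
            )
        return [aff[p] for p in peptides]


def predict_binding(
    peptides: Sequence[PeptideCandidate],
    alleles: Sequence[str],
    predictor: Optional[AffinityPredictor] = None,
    cfg: Optional[PipelineConfig] = None,
) -> list[BindingCall]:
    """One binding call per (peptide, allele); binder iff affinity is
    strictly below ``cfg.affinity_threshold_nM``."""
    cfg = cfg or PipelineConfig()
    predictor = predictor or StubPredictor()
    for a in alleles:
        if not _ALLELE_RE.match(a):
            raise ValueError(f"malformed HLA allele name {a!r} (want e.g. HLA-A*02:01)")
    calls: list[BindingCall] = []
    for allele in alleles:
        seqs = [p.sequence for p in peptides]
        if not seqs:
            continue
        affs = predictor.predict(seqs, allele)
        for p, aff in zip(peptides, affs):
            calls.append(
                BindingCall(
                    peptide=p, allele=allele, affinity_nM=float(aff),
                    is_binder=aff < cfg.affinity_threshold_nM,
                )
            )
    return calls
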