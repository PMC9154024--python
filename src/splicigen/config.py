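"""Pipeline configuration.

Every named threshold of the method lives in one validated record so that a
run is fully described by a :class:`PipelineConfig` plus its inputs.  The
defaults are the published operating point of the method: a k-mer is
tumor-specific when it occurs at least ``t_min`` times in the tumor read
collection and at most ``n_max`` times in the matched normal; k-mer length is
capped at 90% of read length; a junction is called tumor-specific when it is
supported by at least 20 unique tumor reads, by fewer than 3 normal reads,
and by at least 15 tumor-specific-k-mer-containing reads; sequence-variant
edges need 10 supporting reads (SNVs additionally a binomial tail
p <= 5e-6); and a peptide is a predicted binder below 500 nM.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field


class StrandMode(str, enum.Enum):
    """How read strandedness is handled in k-mer counting.

    ``with_revcomp`` (default) indexes every read together with its reverse
    complement, so counts are strand-symmetric — appropriate for unstranded
    libraries.  ``forward_only`` indexes reads as stored, for stranded data.
    """

    forward_only = "forward_only"
    with_revcomp = "with_revcomp"


class UniqueReadRule(str, enum.Enum):
    """Definition of a "uniquely mapping" read for junction support."""

    nh_eq_1 = "nh_eq_1"
    mapq_ge_threshold = "mapq_ge_threshold"


@dataclass
class PipelineConfig:
    # --- differential k-mer search -------------------------------------
    t_min: int = 21              #: minimum tumor occurrence count
    n_max: int = 3               #: maximum normal occurrence count
    kmer_len_frac: float = 0.90  #: k-mer length cap as fraction of read length

    # --- junction calling ----------------------------------------------
    junction_tumor_min_reads: int = 20  #: >= this many unique tumor reads
    junction_normal_max_reads: int = 3  #: exclusive: normal support must be < this
    path_kmer_read_min: int = 15        #: min junction-spanning k-mer reads

    # --- splice-graph variant edges ------------------------------------
    variant_min_support: int = 10
    snv_p_threshold: float = 5e-6
    snv_error_rate: float = 0.01  #: per-base error rate of the binomial null

    # --- peptide / binding stage ---------------------------------------
    peptide_lengths: frozenset[int] = field(
        default_factory=lambda: frozenset({8, 9, 10, 11})
    )
    affinity_threshold_nM: float = 500.0  #: exclusive binder bound

    # --- read handling --------------------------------------------------
    strand_mode: StrandMode = StrandMode.with_revcomp
    unique_read_rule: UniqueReadRule = UniqueReadRule.nh_eq_1
    mapq_unique_threshold: int = 50  #: MAPQ fallback when NH is absent
    deduplicate_reads: bool = False  #: drop duplicate read sequences before indexing

    # --- simulation harness ---------------------------------------------
    sim_genes_per_chrom: int = 5
    sim_min_isoforms: int = 8
    sim_reads_per_transcript: int = 1000  #: read *pairs* per transcript
    sim_read_len: int = 100
    sim_fragment_mean: float = 250.0
    sim_fragment_sd: float = 25.0
    sim_error_rate: float = 0.001
    truth_min_unique_reads: int = 10  #: junctions with <= this count are filtered

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "t_min": self.t_min,
            "n_max": self.n_max,
            "junction_tumor_min_reads": self.junction_tumor_min_reads,
            "junction_normal_max_reads": self.junction_normal_max_reads,
            "path_kmer_read_min": self.path_kmer_read_min,
            "variant_min_support": self.variant_min_support,
            "sim_genes_per_chrom": self.sim_genes_per_chrom,
            "sim_min_isoforms": self.sim_min_isoforms,
            "sim_reads_per_transcript": self.sim_reads_per_transcript,
            "sim_read_len": self.sim_read_len,
            "truth_min_unique_reads": self.truth_min_unique_reads,
            "mapq_unique_threshold": self.mapq_unique_threshold,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.t_min < 1:
            raise ValueError("t_min must be >= 1")
        if not (0.0 < self.kmer_len_frac <= 1.0):
            raise ValueError("kmer_len_frac must be in (0, 1]")
        if not self.peptide_lengths:
            raise ValueError("peptide_lengths must be nonempty")
        if any(int(l) != l or l < 1 for l in self.peptide_lengths):
            raise ValueError("peptide lengths must be integers >= 1")
        if not self.affinity_threshold_nM > 0:
            raise ValueError("affinity_threshold_nM must be > 0")
        if not (0.0 < self.snv_p_threshold < 1.0):
            raise ValueError("snv_p_threshold must be in (0, 1)")
        if not (0.0 < self.snv_error_rate < 1.0):
            raise ValueError("snv_error_rate must be in (0, 1)")
        if not isinstance(self.strand_mode, StrandMode):
            self.strand_mode = StrandMode(self.strand_mode)
        if not isinstance(self.unique_read_rule, UniqueReadRule):
            self.unique_read_rule = UniqueReadRule(self.unique_read_rule)
        if not isinstance(self.peptide_lengths, frozenset):
            self.peptide_lengths = frozenset(int(l) for l in self.peptide_lengths)

    def max_kmer_len(self, read_len: int) -> int:
        """Length cap for tumor-specific k-mers: floor(kmer_len_frac * read_len)."""
        return int(self.kmer_len_frac * read_len)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
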