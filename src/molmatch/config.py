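"""Simulation and pipeline configuration.

``SimConfig`` holds every knob of the synthetic paired-platform generator:
population structure (high-RNA cells, low-RNA cells, ambient barcodes),
molecule-length range, and the platform asymmetries (short-read size-selection
dropout below ~500 bp, PCR duplication, multi-mapping, TSO/polyA
contamination; long-read TSO-artefact removal and MAS concatenation).
``PipelineConfig`` holds the analysis thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

# DNA form of the 10x template-switching oligo (30-mer).
DEFAULT_TSO = "AAGCAGTGGTATCAACGCAGAGTACATGGG"

BARCODE_LEN = 16
UMI_LEN = 12


@dataclass
class SimConfig:
    """Parameters of the synthetic paired-platform experiment.

    Defaults describe the study conditions the generator emulates: a few
    hundred barcodes with bimodal rank structure, molecule lengths spanning
    2^7-2^11 bp, 2-6 PCR duplicate short reads per molecule, short-read
    dropout below 500 bp, and platform-asymmetric TSO contamination.
    """

    seed: int = 0

    # population structure
    n_cells_high: int = 60
    n_cells_low: int = 30
    n_ambient_barcodes: int = 300
    umis_per_cell_high: float = 150.0
    umis_per_cell_low: float = 25.0
    umis_per_ambient: float = 2.0
    frac_ambient_near: float = 0.3  # ambient barcodes within edit distance < 5 of a cell

    # artefact rates
    tso_rate_high: float = 0.06
    tso_rate_low: float = 0.20
    frac_intrapriming: float = 0.10
    frac_rtswitch: float = 0.02
    frac_lcnc: float = 0.15
    frac_unspliced: float = 0.10

    # short-read platform
    illumina_short_dropout: float = 0.8
    dropout_length: int = 500
    dropout_scale: int = 50
    pcr_dup_range: tuple[int, int] = (2, 6)
    multimap_rate: float = 0.07
    short_read_length: int = 91
    p_missing_cb: float = 0.05   # corrected barcode tag absent -> correction exercised
    p_missing_ub: float = 0.05   # corrected UMI tag absent -> raw-UMI substitution
    barcode_error_rate: float = 0.005
    tso_unmapped_prob: float = 0.5

    # long-read platform
    tso_removal_efficiency: float = 0.98
    long_unmapped_rate: float = 0.004
    mas_segments: int = 16

    # reference shape
    n_genes: int = 42
    n_chromosomes: int = 3
    min_length_log2: float = 7.0
    max_length_log2: float = 11.0
    # when set, artefact-prone genes draw their length from the upper range
    # [artefact_gene_min_log2, max_length_log2] (length-biased filtering)
    artefact_gene_min_log2: float | None = None
    # genes per artefact role (A-tract / RT-repeat / long-intron); None uses
    # n_genes // 7 capped at 6
    n_artefact_genes_per_role: int | None = None

    tso_sequence: str = DEFAULT_TSO
    whitelist_decoys: int = 400

    def validate(self) -> None:
        probs = {
            "tso_rate_high": self.tso_rate_high,
            "tso_rate_low": self.tso_rate_low,
            "frac_intrapriming": self.frac_intrapriming,
            "frac_rtswitch": self.frac_rtswitch,
            "frac_lcnc": self.frac_lcnc,
            "frac_unspliced": self.frac_unspliced,
            "illumina_short_dropout": self.illumina_short_dropout,
            "multimap_rate": self.multimap_rate,
            "barcode_error_rate": self.barcode_error_rate,
            "tso_removal_efficiency": self.tso_removal_efficiency,
            "long_unmapped_rate": self.long_unmapped_rate,
            "frac_ambient_near": self.frac_ambient_near,
            "p_missing_cb": self.p_missing_cb,
            "p_missing_ub": self.p_missing_ub,
            "tso_unmapped_prob": self.tso_unmapped_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if (self.frac_intrapriming + self.frac_rtswitch + self.frac_lcnc
                + self.frac_unspliced) > 1.0:
            raise ValueError("artefact fractions sum to more than 1")
        lo, hi = self.pcr_dup_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid pcr_dup_range {self.pcr_dup_range}")
        if self.mas_segments < 1:
            raise ValueError("mas_segments must be >= 1")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("reference must have at least one gene and one chromosome")
        if self.min_length_log2 >= self.max_length_log2:
            raise ValueError("length range is empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pcr_dup_range"] = list(self.pcr_dup_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "pcr_dup_range" in d:
            d["pcr_dup_range"] = tuple(d["pcr_dup_range"])
        return cls(**d)


@dataclass
class PipelineConfig:
    """Analysis thresholds used downstream of the generator."""

    # preprocessing
    barcode_prefix: str = ""          # "" disables prefix subsampling
    # annotation
    exon_overlap_frac: float = 0.5
    end_tolerance_5p: int = 50
    end_tolerance_3p: int = 50
    intrapriming_window: int = 20
    intrapriming_a_frac: float = 0.6
    rt_repeat_len: int = 8
    rt_window: int = 10
    lcnc_min_coverage: int = 3
    min_identity: float = 0.9
    # cell calling / QC
    rescue_min_count: int = 10
    empty_quantile: float = 95.0
    empty_divisor: float = 20.0
    empty_min_dist: int = 5
    empty_cap: int = 2000
    tso_max_mismatch: int = 3
    polya_run: int = 15
    polya_max_interrupt: int = 1
    # comparison
    dispersion: float = 0.1
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    scale_factor: float = 1e4
    long_gene_threshold: int = 1500
    n_hvg: int = 3000
    n_pcs: int = 30
    embed_method: str = "pca"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)
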