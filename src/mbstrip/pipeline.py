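"""End-to-end design pipeline: align -> conserve -> design -> evaluate.

Runs every stage on one labeled panel and writes diff-able text artifacts
(tab-delimited tables and FASTA).  Outputs carry no timestamps, so
re-running with unchanged inputs reproduces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .align import (
    build_msa,
    consensus_in_reference_frame,
    conservation_profile,
    write_aligned_fasta,
)
from .assay import DEFAULT_SIGNAL_RULES, SignalRules, evaluate_panel, strip_table
from .binding import BindingModelParams, params_from_file
from .errors import DesignError
from .panel import ReferencePanel, TARGET, count_group, load_panel_config, read_fasta_panel
from .peptides import DEFAULT_RULES, PeptideDesignRules, design_peptide, peptides_to_fasta
from .regions import DEFAULT_FLANK_WIDTH
from .sandwich import all_perfect_pairs, binding_matrix, select_sandwich_pair

logger = logging.getLogger("mbstrip")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    fasta: str | Path
    config: str | Path
    out_dir: str | Path
    params_file: str | Path | None = None
    reference_id: str | None = None
    flank_width: int = DEFAULT_FLANK_WIDTH
    peptide_rules: PeptideDesignRules = DEFAULT_RULES
    signal_rules: SignalRules = DEFAULT_SIGNAL_RULES


@dataclass(frozen=True)
class PipelineResult:
    """Summary of a completed run (artifact paths plus headline numbers)."""

    detect_region: int
    capture_region: int
    peptides: tuple[str, ...]
    sensitivity: float
    specificity: float
    artifacts: tuple[str, ...]


def run_design_pipeline(
    config: RunConfig, panel: ReferencePanel | None = None
) -> PipelineResult:
    """Run the full pipeline and write artifacts to ``config.out_dir``.

    ``panel`` may be passed directly (e.g. a packaged fixture); otherwise
    it is read from ``config.fasta`` + ``config.config``.  Raises
    :class:`DesignError` when no region pair separates the groups.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if panel is None:
        logger.info("stage=load fasta=%s config=%s", config.fasta, config.config)
        panel = read_fasta_panel(config.fasta, load_panel_config(config.config))
    panel.validate_for_design()

    params = (
        params_from_file(config.params_file)
        if config.params_file
        else BindingModelParams()
    )

    logger.info("stage=align reference=%s n=%d", config.reference_id, len(panel))
    msa = build_msa(panel, config.reference_id)
    write_aligned_fasta(msa, out / "msa.fasta")

    logger.info("stage=conserve group=%s", TARGET)
    profile = conservation_profile(msa, TARGET, panel)
    profile.to_csv(out / "conservation.tsv", sep="\t", index=False)

    logger.info("stage=binding flank_width=%d", config.flank_width)
    matrix = binding_matrix(panel, msa, params, config.flank_width)
    matrix.to_csv(out / "binding_matrix.tsv", sep="\t", index=False)

    logger.info("stage=design")
    design = select_sandwich_pair(panel, msa, params, config.flank_width)
    if design is None:
        raise DesignError("no sandwich pair separates target from off-target species")
    perfect = all_perfect_pairs(panel, msa, params, config.flank_width)

    consensus = consensus_in_reference_frame(msa, TARGET, panel)
    peptides = [
        design_peptide(consensus, region, config.peptide_rules)
        for region in (design.detect_region, design.capture_region)
    ]
    peptides_to_fasta(peptides, out / "peptides.fasta")

    report_lines = [
        f"# mbstrip {__version__} design report",
        f"panel\t{panel.name}",
        f"n_target\t{count_group(panel, 'target')}",
        f"n_offtarget\t{count_group(panel, 'offtarget')}",
        f"detect_region\t{design.detect_region.index}\t{design.detect_region.core_sequence}",
        f"capture_region\t{design.capture_region.index}\t{design.capture_region.core_sequence}",
        f"margin\t{design.margin:g}",
        "perfect_pairs\t"
        + ",".join(f"({d},{c})" for d, c in sorted(r.pair for r in perfect)),
    ]
    for pep in peptides:
        report_lines.append(f"peptide_region{pep.region.index}\t{pep.sequence}")
    (out / "design_report.tsv").write_text("\n".join(report_lines) + "\n")

    logger.info("stage=evaluate")
    metrics = evaluate_panel(
        panel, design, msa, params, config.signal_rules, config.flank_width
    )
    calls = strip_table(
        panel, design, msa, params, config.signal_rules, config.flank_width
    )
    calls.to_csv(out / "strip_calls.tsv", sep="\t", index=False)
    metrics_lines = [
        "metric\tvalue",
        f"true_positive\t{metrics.true_positive}",
        f"false_negative\t{metrics.false_negative}",
        f"true_negative\t{metrics.true_negative}",
        f"false_positive\t{metrics.false_positive}",
        f"sensitivity\t{metrics.sensitivity:.4f}",
        f"specificity\t{metrics.specificity:.4f}",
    ]
    (out / "metrics.tsv").write_text("\n".join(metrics_lines) + "\n")

    artifacts = (
        "msa.fasta",
        "conservation.tsv",
        "binding_matrix.tsv",
        "design_report.tsv",
        "peptides.fasta",
        "strip_calls.tsv",
        "metrics.tsv",
    )
    return PipelineResult(
        detect_region=design.detect_region.index,
        capture_region=design.capture_region.index,
        peptides=tuple(p.sequence for p in peptides),
        sensitivity=metrics.sensitivity,
        specificity=metrics.specificity,
        artifacts=tuple(str(out / a) for a in artifacts),
    )
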