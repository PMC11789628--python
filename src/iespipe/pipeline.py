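"""End-to-end orchestration: simulate -> detect -> count -> score -> profile.

``run_pipeline`` executes the whole analysis on one configuration and
writes plain-text artifacts (FASTA/GFF3/FASTQ/BED/TSV) plus a JSON
summary.  Everything is deterministic given the configured seed; every
output TSV carries a header comment with the config hash and seed so
runs can be traced back to their configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import altclass, chromatin, junctions, retention, simulate, spectrum, srna
from .genome import GenomePair, write_fasta, write_ies_bed6, write_ies_gff3
from .simulate import GroundTruth, SimConfig

__all__ = ["RunConfig", "PipelineError", "ConfigError", "run_pipeline", "load_config"]

log = logging.getLogger("iespipe")

#: synthetic stand-in for the L4440 feeding-vector sequence (generated
#: at run time from a fixed seed; not the real plasmid)
def synthetic_vector(length: int = 2000, seed: int = 424243) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and config hash."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "iespipe_out"
    # detection parameters
    anchor_k: int = 25
    window_W: int = 20
    min_alt_len: int = 2
    max_mismatch: int = 1
    min_anchor: int = 10
    min_cov: int = 5
    # analysis thresholds
    irs_threshold: float = 0.2
    length_threshold: int = 200
    forbidden_band: tuple[int, int] = (34, 44)
    # sRNA settings
    sirna_length: int = 23
    srna_length_range: tuple[int, int] = (15, 35)
    sample: str = "sample"

    def __post_init__(self) -> None:
        # detection geometry feeds the generator's candidate enumeration
        self.sim.anchor_k = self.anchor_k
        self.sim.window_W = self.window_W
        self.sim.min_alt_len = self.min_alt_len

    def config_hash(self) -> str:
        """Fingerprint of the scientific configuration (output path excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config file, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    data = dict(data)
    sim_data = data.pop("sim", {})
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(sim_data) - sim_fields
    if unknown:
        raise ConfigError(f"unknown sim config keys: {sorted(unknown)}")
    run_fields = {f.name for f in dataclasses.fields(RunConfig)} - {"sim"}
    unknown = set(data) - run_fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        sim = SimConfig(**{
            k: (
                [tuple(x) for x in v]
                if k in ("length_spec", "srna_classes") and v is not None
                else v
            )
            for k, v in sim_data.items()
        })
        for key in ("forbidden_band", "srna_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return RunConfig(sim=sim, **data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _stage(name: str, cfg_hash: str):
    """Context manager logging stage timing and wrapping failures."""
    import contextlib

    @contextlib.contextmanager
    def _cm():
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            yield
        except Exception as exc:
            raise PipelineError(
                f"stage {name!r} failed (config {cfg_hash}): {exc}"
            ) from exc
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)

    return _cm()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline and return (and write) the summary.

    Stages: genome simulation, molecule/read simulation, junction
    detection and event counting, retention scoring, alternative-event
    classification and length spectra, nucleosome density differencing
    (experiment vs a multiplier-free control), and sRNA accounting.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    header = f"config_hash={cfg_hash} seed={config.sim.seed}"
    rngs = config.sim.rng_children(6)
    summary: dict[str, Any] = {
        "config_hash": cfg_hash,
        "seed": config.sim.seed,
        "sample": config.sample,
        "thresholds": {
            "irs_threshold": config.irs_threshold,
            "length_threshold": config.length_threshold,
            "forbidden_band": list(config.forbidden_band),
            "min_cov": config.min_cov,
            "anchor_k": config.anchor_k,
            "window_W": config.window_W,
            "max_mismatch": config.max_mismatch,
        },
    }

    with _stage("simulate_genome", cfg_hash):
        pair, truth = simulate.build_genome(config.sim, rngs[0])
        write_fasta(pair.germline, outdir / "germline.fa")
        write_fasta(pair.somatic, outdir / "somatic.fa")
        write_ies_gff3(pair.annotations, outdir / "ies.gff3")
        write_ies_bed6(pair.annotations, outdir / "ies.bed")
        summary["n_ies"] = len(pair.annotations)

    with _stage("simulate_reads", cfg_hash):
        molecules = simulate.simulate_molecules(pair, truth, config.sim, rngs[1])
        reads = simulate.simulate_reads(
            molecules,
            config.sim.read_len,
            config.sim.depth,
            config.sim.error_rate,
            rngs[2],
        )
        simulate.write_fastq(reads, outdir / "reads.fastq")
        _write_truth_tsv(truth, outdir / "ground_truth.tsv", header)
        summary["n_reads"] = len(reads)

    with _stage("detect", cfg_hash):
        library = junctions.build_junction_library(
            pair,
            anchor_k=config.anchor_k,
            window_W=config.window_W,
            min_alt_len=config.min_alt_len,
        )
        assignments = junctions.assign_reads(
            reads, library, config.max_mismatch, config.min_anchor
        )
        counts = junctions.count_events(assignments, pair.annotations)
        junctions.write_counts_tsv(counts, outdir / "event_counts.tsv", header)
        summary["n_ambiguous"] = counts.n_ambiguous
        summary["n_unassigned"] = counts.n_unassigned

    with _stage("score", cfg_hash):
        table = retention.irs_table(counts, config.min_cov, sample=config.sample)
        retention.write_irs_tsv(table, outdir / "irs.tsv", header)
        summary["irs"] = retention.irs_summary(table)

    with _stage("altclass", cfg_hash):
        events = altclass.events_from_counts(counts, pair.annotations)
        altclass.write_events_tsv(events, outdir / "alt_events.tsv", header)
        pct_legacy = altclass.pct_alt_per_ies(counts, "legacy")
        pct_incl = altclass.pct_alt_per_ies(counts, "inclusive")
        summary["alt"] = {
            "n_variants": len(events),
            "pct_mean_legacy": _nan_none(pct_legacy.mean()),
            "pct_mean_inclusive": _nan_none(pct_incl.mean()),
            "shares_reads": altclass.event_type_shares(events, "reads").to_dict(),
            "shares_variants": altclass.event_type_shares(events, "variants").to_dict(),
        }

    with _stage("spectrum", cfg_hash):
        model = spectrum.default_peak_model()
        ref_lengths = [a.excised_len for a in pair.annotations]
        alt_lengths = [ev.length for ev in events for _ in range(ev.count)]
        period = spectrum.periodicity_estimate(ref_lengths, model=model)
        origin = spectrum.origin_of_forbidden(events, pair.annotations, model)
        spectrum.length_histogram(ref_lengths, model).to_csv(
            outdir / "length_hist_reference.tsv", sep="\t", index=False
        )
        if alt_lengths:
            spectrum.length_histogram(alt_lengths, model).to_csv(
                outdir / "length_hist_alt.tsv", sep="\t", index=False
            )
        summary["spectrum"] = {
            "forbidden_fraction_reference": spectrum.forbidden_fraction(
                ref_lengths, model
            ),
            "forbidden_fraction_alt": spectrum.forbidden_fraction(alt_lengths, model),
            "periodicity_bp": None if period is None else period.period,
            "periodicity_confident": None if period is None else period.confident,
            "origin_of_forbidden": origin.to_dict(),
            "min_reference_len": int(min(ref_lengths)) if ref_lengths else None,
            "max_reference_len": int(max(ref_lengths)) if ref_lengths else None,
        }

    with _stage("nucdens", cfg_hash):
        frags_exp = simulate.simulate_nucleosome_fragments(
            pair, truth, config.sim, rngs[3]
        )
        ctrl_truth = GroundTruth(
            ies_ids=truth.ies_ids,
            retention_prob=truth.retention_prob,
            alt_prob=truth.alt_prob,
            density_multiplier=np.ones_like(truth.density_multiplier),
        )
        frags_ctrl = simulate.simulate_nucleosome_fragments(
            pair, ctrl_truth, config.sim, rngs[4]
        )
        simulate.write_fragments_bed(frags_exp, outdir / "nucleosomes_exp.bed")
        simulate.write_fragments_bed(frags_ctrl, outdir / "nucleosomes_ctrl.bed")
        genome_len = pair.germline_length
        dens_exp = chromatin.ies_density(
            frags_exp, pair.annotations, genome_len, sample="exp"
        )
        dens_ctrl = chromatin.ies_density(
            frags_ctrl, pair.annotations, genome_len, sample="ctrl"
        )
        diffs, diff_summary = chromatin.density_difference(dens_exp, dens_ctrl)
        strat, strat_summary = chromatin.stratify(
            diffs,
            table,
            length_threshold=config.length_threshold,
            irs_threshold=config.irs_threshold,
        )
        strat.to_csv(outdir / "density_strata.tsv", sep="\t", na_rep="NA")
        summary["nucleosome"] = {
            "diff": diff_summary,
            "strata": {
                f"{row.irs_group}_{row.len_group}": {
                    "n": int(row.n),
                    "mean_diff": float(row.mean_diff),
                }
                for row in strat_summary.itertuples()
            },
            "n_irs_undefined": strat.attrs["n_undefined"],
        }

    with _stage("srna", cfg_hash):
        vector = synthetic_vector()
        ies_seqs = [pair.ies_sequence(a, include_right_ta=True) for a in pair.annotations]
        sources = {
            "vector": [vector],
            "MAC": list(pair.somatic.values()),
            "IES": ies_seqs,
        }
        srna_reads = simulate.simulate_srna(config.sim.srna_classes, sources, rngs[5])
        simulate.write_srna_fasta(srna_reads, outdir / "srna.fasta")
        counts_srna = srna.classify_srna(
            srna_reads,
            [vector],
            list(pair.somatic.values()),
            ies_seqs,
            length_range=config.srna_length_range,
            sample=config.sample,
        )
        counts_srna.to_dataframe().to_csv(
            outdir / "srna_counts.tsv", sep="\t", index=False
        )
        norm = srna.normalize_by_sirna(counts_srna, sirna_length=config.sirna_length)
        summary["srna"] = {
            "total": counts_srna.total(),
            "dropped": counts_srna.dropped,
            "mac_normalized": {
                int(k): _nan_none(v) for k, v in norm.to_dict().items()
            },
        }

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _nan_none(x: float) -> float | None:
    return None if x != x else float(x)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_truth_tsv(truth: GroundTruth, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("molecule_id\ties_id\toutcome\talt_left\talt_right\n")
        for mol in truth.molecules:
            a, b = mol.alt_pair if mol.alt_pair else (".", ".")
            fh.write(f"{mol.id}\t{mol.ies_id}\t{mol.outcome}\t{a}\t{b}\n")
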