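"""Whole-pipeline orchestration with deterministic, provenance-stamped outputs.

The report stage wires the packaged El Jadida fixture (or any population
table) through classification, diversity/neutrality statistics, and
haplogroup frequency tabulation, writing plain TSV tables whose header
comments record every policy parameter and seed so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import compute_diversity
from .haplogroups import (
    MotifTree,
    classify_all,
    load_default_tree,
    load_motif_tree,
    macro_pool,
    tabulate,
)
from .notation import DistancePolicy, HVRI, load_eljadida_fixture, read_population_table

__all__ = ["RunConfig", "StageError", "run_eljadida_report", "run_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a report run."""

    output_dir: Path
    input_table: Path | None = None  # None -> packaged El Jadida fixture
    motif_tree: Path | None = None  # None -> packaged tree
    policy: DistancePolicy = field(default_factory=DistancePolicy)
    pvalue_reps: int = 1000
    seed: int = 0

    def provenance(self) -> str:
        pol = dataclasses.asdict(self.policy)
        pol["excluded_positions"] = sorted(pol["excluded_positions"])
        return (
            f"mthaplopop {__version__}\n"
            f"input: {self.input_table or 'packaged El Jadida fixture'}\n"
            f"motif tree: {self.motif_tree or 'packaged'}\n"
            f"policy: {pol}\n"
            f"pvalue_reps: {self.pvalue_reps}  seed: {self.seed}"
        )


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w", newline="") as fh:
        for line in provenance.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def run_report(cfg: RunConfig) -> dict[str, Path]:
    """Classify, summarize diversity, and tabulate frequencies for one table.

    Writes ``assignments.tsv``, ``diversity.tsv`` and ``frequencies.tsv``
    into the output directory and returns their paths.  On stage failure
    every file written so far is removed and a stage-named error raised.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    prov = cfg.provenance()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # pragma: no cover - exercised via tests
            for p in written:
                p.unlink(missing_ok=True)
            raise StageError(name, exc) from exc

    def load():
        if cfg.input_table is None:
            return load_eljadida_fixture()
        return read_population_table(cfg.input_table)

    def load_tree():
        if cfg.motif_tree is None:
            return load_default_tree()
        if not Path(cfg.motif_tree).exists():
            raise FileNotFoundError(f"motif tree {cfg.motif_tree} not found")
        return load_motif_tree(cfg.motif_tree)

    tree = stage("configuration", load_tree)
    haps = stage("input", load)

    def do_classify():
        asg = classify_all(haps, tree)
        df = pd.DataFrame(
            {
                "sample_id": [a.sample_id for a in asg],
                "haplogroup": [a.best_node for a in asg],
                "score": [a.score for a in asg],
                "matched": [a.matched for a in asg],
                "mismatches": [a.mismatches for a in asg],
                "ties": [";".join(a.ties) for a in asg],
                "published_label": [h.haplogroup_label or "" for h in haps],
            }
        )
        p = out / "assignments.tsv"
        _write_tsv(df, p, prov)
        written.append(p)
        return asg

    assignments = stage("classify", do_classify)

    def do_diversity():
        res = compute_diversity(
            haps, cfg.policy, HVRI, pvalue_reps=cfg.pvalue_reps, seed=cfg.seed
        )
        pop = haps[0].population or "sample"
        df = pd.DataFrame([{"population": pop, **res.as_dict()}])
        p = out / "diversity.tsv"
        _write_tsv(df, p, prov)
        written.append(p)
        return res

    diversity = stage("diversity", do_diversity)

    def do_frequencies():
        rows = []
        macro = tabulate(assignments, "macro")
        for label, count in macro.counts.items():
            rows.append(
                {
                    "grouping": "macro",
                    "haplogroup": label,
                    "count": count,
                    "denominator": macro.denominator,
                    "percent": 100.0 * count / macro.denominator,
                }
            )
        total = tabulate(assignments, "total-population")
        for label, count in total.counts.items():
            rows.append(
                {
                    "grouping": "total-population",
                    "haplogroup": label,
                    "count": count,
                    "denominator": total.denominator,
                    "percent": 100.0 * count / total.denominator,
                }
            )
        if any(macro_pool(a.best_node) == "L" for a in assignments):
            within = tabulate(assignments, "within-L-pool")
            for label, count in within.counts.items():
                rows.append(
                    {
                        "grouping": "within-L-pool",
                        "haplogroup": label,
                        "count": count,
                        "denominator": within.denominator,
                        "percent": 100.0 * count / within.denominator,
                    }
                )
        p = out / "frequencies.tsv"
        _write_tsv(pd.DataFrame(rows), p, prov)
        written.append(p)

    stage("frequencies", do_frequencies)
    return {
        "assignments": out / "assignments.tsv",
        "diversity": out / "diversity.tsv",
        "frequencies": out / "frequencies.tsv",
    }


def run_eljadida_report(cfg: RunConfig | None = None, output_dir=None, **kwargs) -> dict[str, Path]:
    """The default report over the packaged 81-sample El Jadida fixture."""
    if cfg is None:
        if output_dir is None:
            raise ValueError("provide a RunConfig or an output_dir")
        cfg = RunConfig(output_dir=Path(output_dir), **kwargs)
    if cfg.input_table is not None:
        raise ValueError("run_eljadida_report always uses the packaged fixture")
    return run_report(cfg)
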