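"""End-to-end pipelines binding the stages, with deterministic seeding.

Two arms are provided.  The *evolution* arm simulates trait histories on the
packaged eukaryote tree, emits proteomes, scans them for CAAX boxes, builds
the species × trait profile, and reconstructs gains and losses per trait.
The *proteomics* arm simulates (or ingests) an intensity table and runs
filter → normalize → impute → test → volcano.

Every stochastic stage receives a stage seed derived from the master seed by
hashing ``"{master}:{stage}"``, so a stage's randomness is stable regardless
of stage ordering.  Outputs are staged in a temporary directory and moved
into place on success, so a failing run leaves no partial artifacts; a
manifest JSON records the SHA-256 of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ancestral, io, profiles, proteomics, synthetic
from .caax import detect_caax
from .trees import eukaryote_fixture_tree, write_newick

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "corona_evo_out"
    # evolution arm
    gain_rate: float = 0.05
    loss_rate: float = 0.1
    fragment_fraction: float = 0.0
    # proteomics arm
    n_proteins: int = 300
    n_enriched: int = 5
    effect_log2: float = 4.0
    n_reps: int = 3
    dropout_midpoint: float = 22.0
    dropout_steepness: float = 1.5
    lfc_threshold: float = 2.0
    nlp_threshold: float = 2.0
    test: str = "welch"

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _finalize(tmp: Path, out_dir: Path) -> dict:
    manifest = {
        "artifacts": {
            p.name: _sha256(p) for p in sorted(tmp.iterdir()) if p.is_file()
        }
    }
    (tmp / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    if out_dir.exists():
        shutil.rmtree(out_dir)
    shutil.move(str(tmp), str(out_dir))
    return manifest


def _run_evolution(config: RunConfig, tmp: Path) -> None:
    tree = eukaryote_fixture_tree()
    write_newick(tree, tmp / "tree.nwk")
    family_specs = synthetic.default_family_specs()
    families = list(family_specs)

    # simulate a history per family (plus CAAX subtraits for prenylated ones)
    matrix = pd.DataFrame(index=tree.leaf_names(), columns=[], dtype=str)
    for family in families:
        hist = synthetic.simulate_trait_history(
            tree,
            gain_rate=config.gain_rate,
            loss_rate=config.loss_rate,
            root_state=1,
            seed=stage_seed(config.seed, f"history:{family}"),
        )
        matrix[family] = ["1" if hist.leaf_states[sp] else "0" for sp in matrix.index]
        if family_specs[family].has_caax_trait:
            caax_hist = synthetic.simulate_trait_history(
                tree,
                gain_rate=config.gain_rate,
                loss_rate=config.loss_rate,
                root_state=0,
                dollo_mode=True,
                seed=stage_seed(config.seed, f"history:{family}-CAAX"),
            )
            states = []
            for sp in matrix.index:
                if matrix.loc[sp, family] == "0":
                    states.append("0")
                else:
                    states.append("1" if caax_hist.leaf_states[sp] else "0")
            matrix[f"{family}-CAAX"] = states
    truth_profile = profiles.TraitProfile(matrix)
    truth_profile.to_tsv(tmp / "truth_profile.tsv")

    proteomes, truth = synthetic.emit_proteomes(
        truth_profile,
        family_specs,
        fragment_fraction=config.fragment_fraction,
        seed=stage_seed(config.seed, "proteomes"),
    )
    truth.to_csv(tmp / "truth_orthologs.tsv", sep="\t", index=False, lineterminator="\n")
    for species, records in proteomes.items():
        io.write_fasta(records, tmp / f"proteome_{species}.fasta")

    calls: dict[str, dict[str, list]] = {}
    scanned = []
    for species, records in proteomes.items():
        assigned = synthetic.assign_orthologs(records, family_specs)
        calls[species] = {}
        for family, family_records in assigned.items():
            calls[species][family] = [detect_caax(r) for r in family_records]
            scanned.extend((r, c) for r, c in zip(family_records, calls[species][family]))
    io.write_calls_tsv(scanned, tmp / "caax_calls.tsv")

    profile = profiles.build_profile(calls, list(matrix.index), families)
    profile.to_tsv(tmp / "profile.tsv")

    event_rows = []
    for trait in profile.traits:
        leaf_states = profile.matrix[trait].to_dict()
        root_prior = "free" if trait == "ZW10" else "forced-0"
        result = ancestral.sankoff_reconstruct(
            tree, leaf_states, ancestral.CostModel(root_prior=root_prior)
        )
        newick, events = ancestral.annotate_tree(tree, result)
        (tmp / f"reconstruction_{trait}.nwk").write_text(newick + "\n", encoding="utf-8")
        events.insert(0, "trait", trait)
        event_rows.append(events)
    pd.concat(event_rows, ignore_index=True).to_csv(
        tmp / "events.tsv", sep="\t", index=False, lineterminator="\n"
    )


def _run_proteomics(config: RunConfig, tmp: Path) -> None:
    dropout = synthetic.DropoutModel(
        midpoint=config.dropout_midpoint, steepness=config.dropout_steepness
    )
    table, truth = synthetic.simulate_intensity_table(
        n_proteins=config.n_proteins,
        n_enriched=config.n_enriched,
        effect_log2=config.effect_log2,
        n_reps=config.n_reps,
        dropout_model=dropout,
        seed=stage_seed(config.seed, "intensity"),
    )
    truth.to_csv(tmp / "truth_enrichment.tsv", sep="\t", index=False, lineterminator="\n")
    io.write_intensity_table(table, tmp / "intensities.tsv", tmp / "design.tsv")

    filtered = proteomics.filter_proteins(table)
    normalized = proteomics.normalize_vst(filtered)
    imputed = proteomics.impute_mnar(
        normalized, seed=stage_seed(config.seed, "impute")
    )
    result = proteomics.test_enrichment(
        imputed,
        condition_a=table.conditions[0],
        condition_b=table.conditions[1],
        test=config.test,
        lfc_threshold=config.lfc_threshold,
        nlp_threshold=config.nlp_threshold,
    )
    ranked = proteomics.volcano_table(result)
    ranked.to_csv(tmp / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")
    proteomics.volcano_plot(result, tmp / "volcano.svg")


def run_pipeline(config: RunConfig, arm: str) -> dict:
    """Run one arm end to end; returns the artifact manifest."""
    out_dir = Path(config.out_dir)
    tmp = Path(tempfile.mkdtemp(prefix="corona_evo_"))
    try:
        if arm == "evolution":
            _run_evolution(config, tmp)
        elif arm == "proteomics":
            _run_proteomics(config, tmp)
        else:
            raise ValueError(f"unknown pipeline arm {arm!r}")
        saved = config.to_dict()
        saved.pop("out_dir", None)  # run-local path; keep the manifest portable
        io.save_config(saved, tmp / "config.yaml")
        return _finalize(tmp, out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
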