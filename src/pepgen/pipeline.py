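"""End-to-end orchestration of the peptide design pipeline.

Stage order: prepare -> train -> sample -> dedupe -> describe/compare ->
CD filter -> contact-variance screen -> rank -> cell-penetrating-peptide
fusion.  Every stage writes its artifact into the run directory and the
manifest records seeds, thresholds and the candidate funnel; re-running the
same config reproduces every output byte-identically.

When no experimental inputs are configured, the corpus and the screening
pool come from the :mod:`pepgen.synth` fixtures, and each candidate's
secondary-structure composition for the CD stage is a sequence-derived
helical-propensity heuristic (a stand-in for a 3-D structure predictor,
which is out of scope).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cdspec, descriptors, generator, mdscreen, synth
from .config import PipelineConfig
from .corpus import encode, length_filter, read_fasta, redundancy_reduce, write_fasta

logger = logging.getLogger(__name__)

#: Chou–Fasman-like helix formers used by the heuristic SS assignment.
_HELIX_FORMERS = frozenset("AELMQKRH")


def ss_heuristic(seq: str) -> cdspec.SSComposition:
    """Sequence-derived 3-class composition: helix fraction from the share
    of helix-forming residues, a small fixed sheet share, remainder coil."""
    helix = sum(aa in _HELIX_FORMERS for aa in seq) / len(seq)
    sheet = min(0.2, 1.0 - helix)
    return cdspec.SSComposition(
        {"helix": helix, "sheet": sheet, "coil": 1.0 - helix - sheet}
    )


def _loss_trace_csv(trace: generator.LossTrace, path: Path) -> None:
    df = pd.DataFrame({
        "epoch": np.arange(1, len(trace.train_loss) + 1),
        "train_loss": trace.train_loss,
    })
    if trace.val_loss:
        df["val_loss"] = trace.val_loss
    df.to_csv(path, index=False)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "format_version": cfg.format_version,
        "seed": cfg.seed,
        "thresholds": {
            "identity": cfg.corpus.identity_threshold,
            "variance_cutoff": cfg.screening.variance_cutoff,
            "energy_cutoff_kcal": cfg.screening.energy_cutoff_kcal,
            "top_k": cfg.screening.top_k,
            "lambda_nm": cfg.cd.lambda_nm,
            "learning_rate": cfg.model.learning_rate,
            "dropout": list(cfg.model.dropout),
            "units": cfg.model.units,
            "layers": cfg.model.layers,
        },
        "funnel": {},
        "artifacts": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["artifacts"][stage] = path.name

    try:
        # -- stage 1: corpus preparation ----------------------------------
        if cfg.corpus.input_fasta:
            raw = read_fasta(cfg.corpus.input_fasta, provenance="training")
        else:
            raw = synth.synth_corpus(synth.SynthSpec(
                seed=cfg.seed, n=cfg.corpus.synth_n,
                length_range=(cfg.corpus.min_len, cfg.corpus.max_len),
                motif=cfg.corpus.synth_motif,
            ))
        clean = length_filter(raw, cfg.corpus.min_len, cfg.corpus.max_len)
        clean = redundancy_reduce(clean, cfg.corpus.identity_threshold)
        clean_path = out / "clean.fasta"
        write_fasta(clean, clean_path)
        record("prepare", clean_path)
        manifest["funnel"]["training_in"] = len(raw)
        manifest["funnel"]["training_clean"] = len(clean)

        # -- stage 2: training --------------------------------------------
        batch = encode(clean)
        model_cfg = generator.ModelConfig(
            layers=cfg.model.layers,
            units_per_layer=cfg.model.units,
            dropout_per_layer=tuple(cfg.model.dropout),
            learning_rate=cfg.model.learning_rate,
            forget_gate_bias=cfg.model.forget_gate_bias,
            epochs=cfg.model.epochs,
            seed=cfg.seed,
        )
        state, trace = generator.train(batch, model_cfg)
        ckpt_path = out / "model.ckpt"
        generator.save_checkpoint(state, ckpt_path)
        _loss_trace_csv(trace, out / "loss_trace.csv")
        record("train", ckpt_path)
        manifest["funnel"]["final_train_loss"] = round(trace.train_loss[-1], 6)

        # -- stage 3/4: sampling and deduplication ------------------------
        raw_draws = generator.sample(
            state, cfg.sampling.n_draws, cfg.sampling.temperature,
            cfg.sampling.max_len, seed=cfg.seed + 1,
        )
        write_fasta(raw_draws, out / "sampled.fasta")
        record("sample", out / "sampled.fasta")
        novel = generator.dedupe_against(raw_draws, clean)
        write_fasta(novel, out / "generated.fasta")
        record("dedupe", out / "generated.fasta")
        manifest["funnel"]["draws"] = len(raw_draws)
        manifest["funnel"]["unique_novel"] = len(novel)
        if len(novel) == 0:
            raise RuntimeError("no unique novel sequences sampled")

        # -- stage 5: descriptors, comparison, distances ------------------
        lengths = [len(p) for p in clean]
        rand = descriptors.random_baseline(cfg.compare.n_random, lengths,
                                           seed=cfg.seed + 2)
        helical = descriptors.helical_baseline(cfg.compare.n_helical, lengths,
                                               seed=cfg.seed + 3)
        tables = {}
        for name, corp in [("train", clean), ("gen", novel),
                           ("random", rand), ("helical", helical)]:
            tables[name] = descriptors.describe(corp)
            tables[name].to_csv(out / f"descriptors_{name}.csv")
        comparison = descriptors.compare_tables(
            tables["train"], tables["gen"],
            features=descriptors.DISTANCE_FEATURES,
        )
        comparison.to_csv(out / "comparison_table.csv")
        record("compare", out / "comparison_table.csv")

        scaling = descriptors.fit_scaling(tables["train"][descriptors.DISTANCE_FEATURES])
        ref_scaled = descriptors.apply_scaling(tables["train"], scaling)
        dist_summary = {}
        for name in ("gen", "random", "helical"):
            scaled = descriptors.apply_scaling(tables[name], scaling)
            _, mean, sd = descriptors.euclidean_to_centroid(scaled, ref_scaled)
            dist_summary[name] = {"mean": round(mean, 6), "sd": round(sd, 6)}
        (out / "distances.json").write_text(
            json.dumps(dist_summary, indent=2, sort_keys=True) + "\n")
        record("distances", out / "distances.json")
        manifest["funnel"]["centroid_distance"] = dist_summary

        # -- stage 6: CD filter -------------------------------------------
        if not cfg.cd.enabled:
            _finish(manifest, out)
            return out
        basis = synth.synth_basis(seed=cfg.seed)
        ref_ss = cdspec.SSComposition({
            "helix": cfg.cd.reference_helix_fraction,
            "sheet": 0.1,
            "coil": 1.0 - cfg.cd.reference_helix_fraction - 0.1,
        })
        reference = cdspec.compute_spectrum(ref_ss, basis)
        cdspec.save_spectrum(reference, out / "reference_spectrum.dat")
        candidates = [
            (p.id, cdspec.compute_spectrum(ss_heuristic(p.sequence), basis))
            for p in novel
        ]
        survivors = cdspec.filter_by_reference(
            candidates, reference, cfg.cd.lambda_nm, invert=cfg.cd.invert)
        (out / "cd_pass.txt").write_text("\n".join(survivors) + "\n")
        record("cdfilter", out / "cd_pass.txt")
        manifest["funnel"]["cd_pass"] = len(survivors)

        # -- stage 7/8: contact-variance screen, ranking, fusion ----------
        if not cfg.screening.enabled:
            _finish(manifest, out)
            return out
        scr = cfg.screening
        by_id = {p.id: p.sequence for p in novel}
        if scr.contacts_csv and scr.energies_csv:
            records = load_contact_records(scr.contacts_csv, scr.energies_csv)
        else:
            pool_ids = [s for s in survivors if s in by_id][: scr.n_total]
            n_total = len(pool_ids)
            if n_total == 0:
                raise RuntimeError("no CD-passing candidates to screen")
            n_low = min(scr.n_low_variance,
                        round(n_total * scr.n_low_variance / scr.n_total))
            raw_records = synth.synth_contact_records(
                seed=cfg.seed + 4, n_total=n_total, n_low_variance=n_low,
                cutoff=scr.variance_cutoff,
            )
            records = [
                (pid, series, energy)
                for pid, (_, series, energy) in zip(pool_ids, raw_records)
            ]
        screened = mdscreen.screen(
            [(pid, s, e) for pid, s, e in records],
            variance_cutoff=scr.variance_cutoff,
            energy_cutoff_kcal=scr.energy_cutoff_kcal,
        )
        top = mdscreen.rank_top_k(screened, scr.top_k)
        report = mdscreen.screen_report(screened)
        report.to_csv(out / "screen_report.csv", index=False)
        record("screen", out / "screen_report.csv")
        manifest["funnel"]["screened"] = len(screened)
        manifest["funnel"]["variance_pass"] = int(
            sum(r.passes_variance for r in screened))
        manifest["funnel"]["both_pass"] = int(
            sum(r.passes_variance and r.passes_energy for r in screened))
        manifest["funnel"]["top_k"] = len(top)

        rows = []
        for r in top:
            seq = by_id.get(r.peptide_id)
            rows.append({
                "rank": r.rank,
                "peptide_id": r.peptide_id,
                "sequence": seq,
                "fused_sequence": mdscreen.fuse_cpp(seq, scr.cpp) if seq else None,
                "contact_variance": r.contact_variance,
                "binding_energy_kcal_mol": r.binding_energy,
            })
        pd.DataFrame(rows).to_csv(out / "top_candidates.csv", index=False)
        record("rank_fuse", out / "top_candidates.csv")

        _finish(manifest, out)
        return out
    except Exception as exc:
        manifest["error"] = str(exc)
        _finish(manifest, out)
        raise


def load_contact_records(
    contacts_csv: str | Path, energies_csv: str | Path
) -> list[tuple[str, mdscreen.ContactSeries, float | None]]:
    """Load per-frame contact counts and binding energies from CSV.

    ``contacts_csv`` columns: peptide_id, frame, count.  ``energies_csv``
    columns: peptide_id, energy_kcal_mol.  Peptides without an energy entry
    get ``None`` (they will fail the energy criterion, flagged).
    """
    contacts = pd.read_csv(contacts_csv)
    energies = pd.read_csv(energies_csv).set_index("peptide_id")["energy_kcal_mol"]
    records = []
    for pid, grp in contacts.groupby("peptide_id", sort=False):
        counts = grp.sort_values("frame")["count"].to_numpy()
        energy = float(energies[pid]) if pid in energies.index else None
        records.append((str(pid), mdscreen.ContactSeries(str(pid), counts), energy))
    return records


def _finish(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
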