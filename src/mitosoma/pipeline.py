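"""End-to-end orchestration of the somatic mtDNA analysis.

``run_all`` composes the full analysis — RNA confirmation, annotation,
per-cancer summary, heteroplasmy/selection statistics, strand-resolved
spectrum and enrichment, segment densities, DNA/RNA imbalance with
regional enrichment, and tRNA structural-impact scoring with the group
comparison — and returns a manifest holding parameters, headline results
and the paths of every emitted table.  Identical inputs and seed produce
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import Annotator, annotate_catalogue
from .catalogue import (
    Catalogue,
    filter_rna_confirmed,
    summarize_by_cancer,
    tumors_with_mutation,
    write_catalogue,
)
from .imbalance import detect_imbalanced, dna_rna_correlation, region_enrichment
from .reference import base_composition, load_cloverleafs, load_features, load_genome
from .selection import chi2_yates, expected_nonsyn_fraction, heteroplasmy_summary, ks_two_sample
from .signature import (
    dipyrimidine_fraction,
    enrichment,
    expected_fractions,
    gc_pair_enrichment,
    gc_pair_fraction,
    segment_signatures,
    strand_spectrum,
)
from .simulate import TUMORS_PER_TYPE
from .trna_structure import (
    background_distribution,
    compare_groups,
    score_trna_variants,
)

__all__ = ["RunManifest", "run_all"]


@dataclass
class RunManifest:
    """Parameters, outputs and headline results of one pipeline run."""

    seed: int
    parameters: dict
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def run_all(
    cat: Catalogue,
    out_dir=None,
    seed: int = 0,
    genome=None,
    features=None,
    cloverleafs=None,
    shuffles: int = 50,
    threshold: float = 0.3,
    n_segments: int = 50,
    exclude_dloop: bool = False,
    min_rna_vaf: float = 0.02,
) -> RunManifest:
    """Run every analysis stage on a catalogue; optionally write tables."""
    genome = genome or load_genome()
    features = features or load_features()
    cloverleafs = cloverleafs or load_cloverleafs()
    annotator = Annotator(genome, features)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        seed=seed,
        parameters={
            "shuffles": shuffles,
            "imbalance_threshold": threshold,
            "n_segments": n_segments,
            "exclude_dloop": exclude_dloop,
            "min_rna_vaf": min_rna_vaf,
            "provenance": cat.provenance,
        },
    )
    res = manifest.results

    def emit(name, obj):
        if out is None:
            return
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False)
        elif isinstance(obj, Catalogue):
            write_catalogue(obj, path)
        manifest.outputs[name] = str(path)
        manifest.log.append(f"wrote {name}")

    # 1. RNA confirmation ---------------------------------------------------
    conf = filter_rna_confirmed(cat, min_rna_vaf=min_rna_vaf)
    res["n_sequenced"] = len(cat)
    res["n_confirmed"] = len(conf)
    res["n_snv"] = len(conf.snvs())
    res["n_indel"] = len(conf.indels())
    res["n_tumors_mutated"] = tumors_with_mutation(conf)
    emit("confirmed_catalogue.tsv", conf)

    # 2. annotation ---------------------------------------------------------
    adf = annotate_catalogue(conf, genome, features, annotator)
    emit("annotated_catalogue.tsv", adf)
    coding = adf[adf.region == "coding"]
    res["n_coding"] = int(len(coding))
    effect_counts = coding.effect.value_counts().to_dict()
    res["effect_counts"] = {k: int(v) for k, v in effect_counts.items()}

    # 3. per-cancer summary -------------------------------------------------
    types = {r.cancer_type for r in conf}
    if types <= set(TUMORS_PER_TYPE):
        tumors_map = dict(TUMORS_PER_TYPE)
    else:  # unknown cohort: count distinct samples per type
        tumors_map = (
            conf.to_frame().groupby("cancer_type").sample_id.nunique().to_dict()
        )
    summary = summarize_by_cancer(conf, tumors_map)
    emit("summary_by_cancer.tsv", summary)
    total = summary[summary.cancer_type == "TOTAL"].iloc[0]
    res["mutations_per_tumor"] = float(total.mutations_per_tumor)
    res["pct_indels"] = float(total.pct_indels)

    # 4. heteroplasmy / selection -------------------------------------------
    sel_rows = []
    all_vafs = [r.vaf_dna for r in conf]
    categories = {
        "all": adf.index,
        "missense": adf.index[adf.effect == "missense"],
        "synonymous": adf.index[adf.effect == "synonymous"],
        "nonsense": adf.index[adf.effect == "nonsense"],
        "frameshift": adf.index[adf.effect == "frameshift"],
        "D-loop": adf.index[adf.region == "D-loop"],
    }
    for label, idx in categories.items():
        if len(idx) == 0:
            continue
        vafs = adf.loc[idx, "vaf_dna"]
        row = {
            "category": label,
            "n": int(len(idx)),
            "mean_vaf": float(vafs.mean()),
            "max_vaf": float(vafs.max()),
            "frac_above_095": float((vafs > 0.95).mean()),
        }
        if label != "all" and 0 < len(idx) < len(adf):
            rest = adf.loc[adf.index.difference(idx), "vaf_dna"]
            ks = ks_two_sample(vafs, rest)
            row["ks_D"] = ks.statistic
            row["ks_p"] = ks.p_value
        sel_rows.append(row)
    sel_df = pd.DataFrame(sel_rows)
    emit("selection.tsv", sel_df)
    res["mean_heteroplasmy"] = float(np.mean(all_vafs))
    res["frac_near_homoplasmy"] = float(np.mean(np.array(all_vafs) > 0.95))
    for label in ("frameshift", "nonsense", "D-loop"):
        sub = sel_df[sel_df.category == label]
        if len(sub):
            res[f"{label.lower().replace('-', '')}_mean"] = float(sub.mean_vaf.iloc[0])
            res[f"{label.lower().replace('-', '')}_max"] = float(sub.max_vaf.iloc[0])
            res[f"{label.lower().replace('-', '')}_ks_p"] = float(sub.ks_p.iloc[0])

    # 5. spectrum, enrichment, chi2 null ------------------------------------
    spec_cat = conf
    if exclude_dloop:
        dloop_idx = set(adf.index[adf.region == "D-loop"])
        spec_cat = Catalogue(
            [r for i, r in enumerate(conf.records) if i not in dloop_idx],
            provenance=f"{conf.provenance} [no D-loop]",
        )
    spec = strand_spectrum(spec_cat)
    comp = base_composition(genome)
    enr = enrichment(spec, expected_fractions(comp))
    emit("spectrum_enrichment.tsv", enr)
    cth = enr[(enr.sub_class == "C>T") & (enr.strand == "H")]
    res["cth_enrichment"] = float(cth.ratio.iloc[0])
    res["modal_class"] = "{}:{}".format(
        *enr.loc[enr["count"].idxmax(), ["sub_class", "strand"]]
    )
    res["gc_pair_fraction"] = gc_pair_fraction(spec)
    res["gc_pair_enrichment"] = gc_pair_enrichment(spec, comp)
    res["dipyrimidine_fraction"] = dipyrimidine_fraction(conf, genome)

    n_nonsyn = sum(effect_counts.get(k, 0) for k in ("missense", "nonsense"))
    n_syn = effect_counts.get("synonymous", 0)
    f0 = expected_nonsyn_fraction(annotator, spec.fractions())
    chi2 = chi2_yates((n_nonsyn, n_syn), f0)
    res["expected_nonsyn_fraction"] = f0
    res["observed_nonsyn_syn"] = (n_nonsyn, n_syn)
    res["chi2_nonsyn_stat"] = chi2.statistic
    res["chi2_nonsyn_p"] = chi2.p_value

    # 6. segment densities --------------------------------------------------
    seg = segment_signatures(conf, genome.length, n_segments)
    emit("segments.tsv", seg)
    dense = seg.loc[seg.n_mutations.idxmax()]
    dloop_feats = features.by_class("D-loop")
    res["densest_segment"] = (int(dense.start), int(dense.end))
    res["densest_segment_in_dloop"] = bool(
        dloop_feats
        and any(
            dloop_feats[0].contains(int(p), genome.length)
            for p in (dense.start, dense.end)
        )
    )

    # 7. DNA/RNA imbalance ---------------------------------------------------
    res["dna_rna_r"] = dna_rna_correlation(conf)
    imb = detect_imbalanced(conf, threshold=threshold)
    emit("imbalanced.tsv", imb)
    res["n_imbalanced"] = len(imb)
    imb_keys = {r.key for r in imb}
    background = conf.subset(lambda r: r.key not in imb_keys)

    def in_trna(rec):
        return any(
            f.feature_class == "tRNA" for f in annotator.features_at(rec.position)
        )

    if len(imb) and len(background):
        fisher, table = region_enrichment(imb, background, in_trna)
        res["n_imbalanced_trna"] = table[0][0]
        res["n_background_trna"] = table[1][0]
        res["n_background"] = table[1][0] + table[1][1]
        res["fisher_table"] = table
        res["fisher_odds"] = fisher.statistic
        res["fisher_p"] = fisher.p_value

    # 8. tRNA structural impact ----------------------------------------------
    rng = np.random.default_rng([seed, 4242])
    bg = background_distribution(
        [c.sequence for c in cloverleafs.values()], shuffles, rng
    )
    scored = score_trna_variants(conf, features, cloverleafs, bg)
    if len(scored):
        scored["processing_defect"] = [
            (s, p, r, a) in {(k[0], k[1], k[2], k[3]) for k in imb_keys}
            for s, p, r, a in zip(
                scored.sample_id, scored.position, scored.ref, scored.alt
            )
        ]
        emit("trna_structure.tsv", scored)
        res["n_trna_snv"] = int(len(scored))
        analyzable = scored[scored.native_ok]
        res["n_trna_analyzable"] = int(len(analyzable))
        res["stem_counts"] = {
            "defect": int((scored[scored.processing_defect].location == "stem").sum()),
            "defect_total": int(scored.processing_defect.sum()),
            "other": int((scored[~scored.processing_defect].location == "stem").sum()),
            "other_total": int((~scored.processing_defect).sum()),
        }
        defect_p = analyzable[analyzable.processing_defect].p_value
        normal_p = analyzable[~analyzable.processing_defect].p_value
        if len(defect_p) and len(normal_p):
            wil = compare_groups(defect_p, normal_p)
            res["wilcoxon_stat"] = wil.statistic
            res["wilcoxon_p"] = wil.p_value
            res["defect_median_d"] = float(
                analyzable[analyzable.processing_defect].d.median()
            )
            res["other_median_d"] = float(
                analyzable[~analyzable.processing_defect].d.median()
            )

    if out is not None:
        manifest.to_json(out / "manifest.json")
        manifest.outputs["manifest.json"] = str(out / "manifest.json")
    return manifest
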