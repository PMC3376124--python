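"""End-to-end orchestration: encode -> rank -> ifs -> winnow -> train ->
predict -> refine -> evaluate, plus the tabular file formats the CLI
subcommands exchange."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .encoding import (
    SampleSet,
    assemble_blocks,
    concat_sample_sets,
    dedupe_samples,
    label_residues,
    make_windows,
)
from .forest import RandomForestDomainClassifier, forest_to_json
from .ifs import ConfusionCounts, IFSRow, ifs_curve, metrics, optimal_set, winnow_final
from .mrmr import MRMRRanker, RankedFeatures
from .refine import (
    CodeTrack,
    codes_from_predictions,
    evaluate_tracks,
    extract_regions,
    refine_track,
)
from .synthetic import GeneratorConfig, SyntheticData, generate, write_fixture

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tabular formats

def write_samples(samples: SampleSet, path) -> None:
    """Wide TSV: provenance columns, label, then one column per feature."""
    df = pd.DataFrame(samples.X, columns=samples.feature_names)
    df.insert(0, "label", samples.y)
    df.insert(0, "window_seq", samples.window_seqs)
    df.insert(0, "center", samples.centers)
    df.insert(0, "protein_id", samples.protein_ids)
    df.to_csv(path, sep="\t", index=False)


def read_samples(path) -> SampleSet:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    meta = ["protein_id", "center", "window_seq", "label"]
    names = [c for c in df.columns if c not in meta]
    w = len(df["window_seq"].iloc[0])
    return SampleSet(
        X=df[names].to_numpy(dtype=float),
        y=df["label"].to_numpy(dtype=int),
        protein_ids=df["protein_id"].tolist(),
        centers=df["center"].to_numpy(dtype=int),
        window_seqs=df["window_seq"].tolist(),
        w=w,
        feature_names=names,
    )


def write_rankings(ranked: RankedFeatures, maxrel_path, mrmr_path) -> None:
    pd.DataFrame(
        [(i + 1, name, d) for i, (name, d) in enumerate(ranked.maxrel)],
        columns=["rank", "feature", "relevance"],
    ).to_csv(maxrel_path, sep="\t", index=False)
    pd.DataFrame(
        ranked.mrmr, columns=["feature", "round", "score"]
    ).to_csv(mrmr_path, sep="\t", index=False)


def read_mrmr_ranking(path) -> list[str]:
    return pd.read_csv(path, sep="\t")["feature"].tolist()


def write_ifs_table(curve: list[IFSRow], path) -> None:
    pd.DataFrame(
        [
            (r.subset_index, r.n_features, r.sensitivity, r.specificity,
             r.accuracy, r.mcc)
            for r in curve
        ],
        columns=["i", "n_features", "sensitivity", "specificity", "accuracy", "mcc"],
    ).to_csv(path, sep="\t", index=False)


def read_ifs_table(path) -> list[IFSRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        IFSRow(int(r.i), int(r.n_features), float(r.sensitivity),
               float(r.specificity), float(r.accuracy), float(r.mcc))
        for r in df.itertuples(index=False)
    ]


def write_tracks(tracks: list[CodeTrack], path) -> None:
    pd.DataFrame(
        [(t.protein_id, t.codes) for t in tracks], columns=["protein_id", "codes"]
    ).to_csv(path, sep="\t", index=False)


def read_tracks(path) -> list[CodeTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "codes": str})
    return [CodeTrack(r.protein_id, r.codes) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# stage helpers

def load_feature_inputs(fasta, domains, pssm_dir, disorder, ss, sa,
                        pssm_columns: str = "scores"):
    """Read and validate every pipeline input; returns (records, blocks)."""
    records = dio.read_fasta(fasta)
    records = dio.read_domain_annotations(domains, records)
    disorder_v = dio.read_residue_table(disorder, "disorder", records)
    ss_v = dio.read_residue_table(ss, "ss", records)
    sa_v = dio.read_residue_table(sa, "sa", records)
    blocks = {}
    for rec in records:
        pssm = dio.read_pssm_ascii(
            Path(pssm_dir) / f"{rec.id}.pssm",
            expected_length=len(rec.sequence),
            columns=pssm_columns,
        )
        blocks[rec.id] = assemble_blocks(
            rec.sequence, pssm, disorder_v[rec.id], ss_v[rec.id], sa_v[rec.id]
        )
    return records, blocks


def encode_proteins(records, blocks, w: int,
                    dedupe_threshold: float | None = None) -> SampleSet:
    """Window every protein and optionally deduplicate."""
    samples = concat_sample_sets([make_windows(r, blocks[r.id], w) for r in records])
    if dedupe_threshold is not None:
        samples = dedupe_samples(samples, dedupe_threshold)
    return samples


def predict_tracks(clf: RandomForestDomainClassifier, samples: SampleSet,
                   feature_idx) -> list[CodeTrack]:
    """Per-protein code tracks from per-residue forest predictions."""
    pred = clf.predict(samples.X[:, np.asarray(feature_idx, dtype=int)])
    tracks = []
    pids = np.asarray(samples.protein_ids)
    for pid in dict.fromkeys(samples.protein_ids):  # preserve order
        mask = pids == pid
        order = np.argsort(samples.centers[mask])
        tracks.append(codes_from_predictions(pid, pred[mask][order] == 1))
    return tracks


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PipelineConfig:
    """Resolved configuration for an end-to-end run.

    Defaults follow the reference protocol: window 13, IFS step 5,
    10-tree forest. ``n_rank`` bounds the number of mRMR rounds (None
    ranks the full 31*w feature set; the IFS curve then has
    floor(31*w/step) points, which is expensive — bound it for quick
    runs). Inputs may be files (fasta/domains/pssm_dir/disorder/ss/sa)
    or a synthetic generator config under ``simulate``.
    """

    window: int = 13
    k_sigma: float = 1.0
    step: int = 5
    n_trees: int = 10
    m_features: int | None = None
    seed: int = 1
    refinement: bool = True
    dedupe_threshold: float | None = None
    n_rank: int | None = None
    train_fraction: float = 0.7
    pssm_columns: str = "scores"
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window size must be odd")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _split_proteins(records, fraction: float, rng):
    ids = [r.id for r in records]
    perm = rng.permutation(len(ids))
    n_train = max(1, int(round(fraction * len(ids))))
    n_train = min(n_train, len(ids) - 1) if len(ids) > 1 else len(ids)
    train = {ids[i] for i in perm[:n_train]}
    return [r for r in records if r.id in train], [r for r in records if r.id not in train]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write its outputs under ``out_dir``.

    Proteins are split into a training and a held-out set; feature
    ranking, the IFS curve and the final winnowed feature set are
    computed on training windows only; the trained forest then predicts
    per-residue tracks for the held-out proteins, which are refined and
    evaluated against the annotation. Returns a results dict with the
    curve, the selected features and the pre/post-refinement metrics.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.simulate is not None:
        sim_cfg = GeneratorConfig(**config.simulate)
        data: SyntheticData = generate(sim_cfg)
        fixture_paths = write_fixture(data, out_dir / "inputs")
        records, blocks = data.records, data.blocks
    elif config.inputs:
        records, blocks = load_feature_inputs(
            config.inputs["fasta"], config.inputs["domains"],
            config.inputs["pssm_dir"], config.inputs["disorder"],
            config.inputs["ss"], config.inputs["sa"],
            pssm_columns=config.pssm_columns,
        )
    else:
        raise ValueError("config must provide either 'simulate' or 'inputs'")

    train_recs, test_recs = _split_proteins(records, config.train_fraction, rng)
    logger.info("training on %d proteins, evaluating on %d", len(train_recs), len(test_recs))
    train_samples = encode_proteins(train_recs, blocks, config.window,
                                    config.dedupe_threshold)
    write_samples(train_samples, out_dir / "samples_train.tsv")

    ranker = MRMRRanker(k_sigma=config.k_sigma, n_select=config.n_rank)
    ranker.fit(train_samples.X, train_samples.y)
    ranked = ranker.ranked_features(train_samples.feature_names)
    write_rankings(ranked, out_dir / "maxrel.tsv", out_dir / "mrmr.tsv")

    cv_seed = int(rng.integers(2**31))
    curve = ifs_curve(
        train_samples.X, train_samples.y, ranked.mrmr_indices,
        l=config.step, seed=cv_seed, n_trees=config.n_trees,
        forest_params={"m_features": config.m_features},
    )
    write_ifs_table(curve, out_dir / "ifs.tsv")
    optimal_idx = optimal_set(curve, ranked.mrmr_indices)
    final_idx = winnow_final(curve, ranked.mrmr_indices, gap=config.step)
    final_names = [train_samples.feature_names[j] for j in final_idx]
    (out_dir / "selected_features.txt").write_text(
        "\n".join(final_names) + "\n", encoding="utf-8"
    )

    clf = RandomForestDomainClassifier(
        n_trees=config.n_trees, m_features=config.m_features,
        random_state=int(rng.integers(2**31)),
    ).fit(train_samples.X[:, final_idx], train_samples.y)
    forest_to_json(clf, out_dir / "model.json", feature_names=final_names)

    eval_recs = test_recs if test_recs else train_recs
    eval_samples = encode_proteins(eval_recs, blocks, config.window)
    tracks = predict_tracks(clf, eval_samples, final_idx)
    write_tracks(tracks, out_dir / "tracks.tsv")

    truth = {r.id: label_residues(r) for r in eval_recs}
    raw_counts = ConfusionCounts()
    for t in tracks:
        raw_counts = raw_counts + evaluate_tracks(t, truth[t.protein_id])
    report_rows = [("no",) + metrics(raw_counts)]

    refined = tracks
    if config.refinement:
        refined = [refine_track(t) for t in tracks]
        write_tracks(refined, out_dir / "refined.tsv")
        ref_counts = ConfusionCounts()
        for t in refined:
            ref_counts = ref_counts + evaluate_tracks(t, truth[t.protein_id])
        report_rows.append(("yes",) + metrics(ref_counts))

    dio.write_regions(
        {t.protein_id: extract_regions(t) for t in refined}, out_dir / "regions.tsv"
    )
    report = pd.DataFrame(
        report_rows,
        columns=["refinement", "sensitivity", "specificity", "accuracy", "mcc"],
    )
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False)

    resolved = asdict(config)
    resolved["cv_seed"] = cv_seed
    with open(out_dir / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)

    return {
        "curve": curve,
        "optimal_features": [train_samples.feature_names[j] for j in optimal_idx],
        "final_features": final_names,
        "report": report,
        "tracks": tracks,
        "refined_tracks": refined,
        "out_dir": out_dir,
    }
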