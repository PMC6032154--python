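"""End-to-end training pipeline and text-based model bundle persistence.

A fitted model bundle is a directory of diffable text files:

    config.json       pipeline configuration + vocabulary checksum
    vocabulary.tsv    feature table (template, residues, column index)
    ranking.tsv       selected vocabulary columns in rank order
    discretizer.json  per-column cutoffs
    mnb.json          priors and per-class log event probabilities

Loading verifies that every part carries the same vocabulary checksum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .discretization import DiscretizationModel, discretize, fit_discretizer
from .encoding import DenseFeatureMatrix, SequenceRecord, encode
from .errors import DataError, IntegrityError, InvalidArgumentError
from .mnb import MNBModel, Prediction, fit_mnb, predict
from .patterns import FeatureVocabulary, admissible_patterns, build_vocabulary
from .selection import anova_f, rank_features

POSITIVE_LABEL = "virion"
NEGATIVE_LABEL = "non-virion"


@dataclass
class PipelineConfig:
    """All knobs of the train/evaluate pipeline, with study defaults."""

    max_residues: int = 3
    max_gaps: int = 2
    n_features: int | None = None  # None = use the full vocabulary
    alpha: float = 1.0
    folds: int = 10
    seed: int = 0
    leakage: str = "fold"  # 'fold' (re-fit per training fold) or 'global'
    residue_policy: str = "reject"

    def validate(self, vocab_size: int | None = None) -> None:
        if self.alpha <= 0:
            raise InvalidArgumentError("alpha must be > 0")
        if self.leakage not in ("fold", "global"):
            raise InvalidArgumentError(f"unknown leakage policy {self.leakage!r}")
        if self.n_features is not None and self.n_features < 1:
            raise InvalidArgumentError("n_features must be >= 1")
        if (
            vocab_size is not None
            and self.n_features is not None
            and self.n_features > vocab_size
        ):
            raise InvalidArgumentError(
                f"n_features={self.n_features} exceeds vocabulary size "
                f"{vocab_size}"
            )

    def to_dict(self) -> dict:
        return {
            "max_residues": self.max_residues,
            "max_gaps": self.max_gaps,
            "n_features": self.n_features,
            "alpha": self.alpha,
            "folds": self.folds,
            "seed": self.seed,
            "leakage": self.leakage,
            "residue_policy": self.residue_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


@dataclass
class FittedPipeline:
    """Vocabulary + ranking + discretizer + classifier, ready to predict."""

    config: PipelineConfig
    vocabulary: FeatureVocabulary
    selected_columns: np.ndarray
    discretizer: DiscretizationModel
    mnb: MNBModel
    f_values: np.ndarray | None = field(default=None, repr=False)

    def predict_records(self, records: list[SequenceRecord]) -> list[Prediction]:
        if not records:
            return []
        matrix = encode(records, self.vocabulary)
        return self.predict_matrix(matrix)

    def predict_matrix(self, matrix: DenseFeatureMatrix) -> list[Prediction]:
        dense = matrix.values[:, self.selected_columns]
        discrete = discretize(dense, self.discretizer)
        return predict(self.mnb, discrete)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        checksum = self.vocabulary.checksum
        self.vocabulary.save(out / "vocabulary.tsv")
        with open(out / "ranking.tsv", "w") as fh:
            fh.write("rank\tcolumn\tf_value\n")
            for r, c in enumerate(self.selected_columns):
                fv = (
                    float(self.f_values[c])
                    if self.f_values is not None
                    else float("nan")
                )
                fh.write(f"{r}\t{int(c)}\t{fv!r}\n")
        self.discretizer.to_json(out / "discretizer.json", checksum)
        self.mnb.to_json(out / "mnb.json", checksum)
        payload = self.config.to_dict()
        payload["vocabulary_checksum"] = checksum
        (out / "config.json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "FittedPipeline":
        bundle = Path(bundle_dir)
        cfg_payload = json.loads((bundle / "config.json").read_text())
        config = PipelineConfig.from_dict(cfg_payload)
        vocab = FeatureVocabulary.load(bundle / "vocabulary.tsv")
        checksum = cfg_payload.get("vocabulary_checksum")
        if vocab.checksum != checksum:
            raise IntegrityError("vocabulary checksum mismatch in bundle")
        for part in ("discretizer.json", "mnb.json"):
            stored = json.loads((bundle / part).read_text())[
                "vocabulary_checksum"
            ]
            if stored != checksum:
                raise IntegrityError(f"{part}: vocabulary checksum mismatch")
        cols = []
        fvals = []
        with open(bundle / "ranking.tsv") as fh:
            next(fh)  # header
            for line in fh:
                _, col, fv = line.rstrip("\n").split("\t")
                cols.append(int(col))
                fvals.append(float(fv))
        return cls(
            config=config,
            vocabulary=vocab,
            selected_columns=np.asarray(cols, dtype=np.int64),
            discretizer=DiscretizationModel.from_json(
                bundle / "discretizer.json"
            ),
            mnb=MNBModel.from_json(bundle / "mnb.json"),
            f_values=None,
        )


def fit_pipeline(
    records: list[SequenceRecord],
    labels: np.ndarray,
    config: PipelineConfig | None = None,
    matrix: DenseFeatureMatrix | None = None,
) -> FittedPipeline:
    """Fit vocabulary -> densities -> ANOVA ranking -> discretizer -> MNB.

    The final model is always fitted on the full training set (the leakage
    policy only affects cross-validation estimates).  Pass a pre-computed
    ``matrix`` to skip re-encoding.
    """
    config = config or PipelineConfig()
    labels = np.asarray(labels)
    if len(records) != len(labels):
        raise InvalidArgumentError("records and labels must align")
    if len(np.unique(labels)) < 2:
        raise DataError("training data must contain both classes")
    vocab = (
        matrix.vocabulary
        if matrix is not None
        else build_vocabulary(
            admissible_patterns(config.max_residues, config.max_gaps)
        )
    )
    config.validate(vocab_size=len(vocab))
    if matrix is None:
        matrix = encode(records, vocab)

    table = anova_f(matrix.values, labels)
    ranked = rank_features(table)
    k = config.n_features or len(vocab)
    cols = ranked[:k]
    disc = fit_discretizer(matrix.values[:, cols])
    discrete = discretize(matrix.values[:, cols], disc)
    model = fit_mnb(discrete, labels, alpha=config.alpha)
    return FittedPipeline(
        config=config,
        vocabulary=vocab,
        selected_columns=cols,
        discretizer=disc,
        mnb=model,
        f_values=table.f_values,
    )
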