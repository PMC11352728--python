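"""Random-forest benchmarking harness: in/out-of-domain cases and controls.

Seven out-of-domain cases probe how far a model trained on some substrates
carries to an unseen one: cases 1-3 train on the two related substrates,
cases 4-6 add the unrelated SM4/SM5 to the training set, and case 7 tries
to predict SM4 from the unrelated SM3 and SM5. Partial out-of-domain
additionally moves a random half of the target substrate's catalysts into
training; in-domain holds out 20% of catalysts for a single substrate and
uses catalyst features only. Classification (high/low conversion) is scored
by balanced accuracy, regression (ddG) by R^2; Gini feature importances are
reported normalized. A Monte-Carlo subset study quantifies how chance
correlation inflates the best observed R^2 on small catalyst subsets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .hte import ee_to_ddg, label_conversion
from .io import HTERecord, records_to_frame

__all__ = [
    "CASES",
    "CaseSpec",
    "ExperimentSpec",
    "HarnessConfig",
    "HarnessData",
    "ModelResult",
    "modeling_frame",
    "build_design_matrix",
    "split",
    "balanced_accuracy",
    "run_experiment",
    "enumerate_experiments",
    "monte_carlo_subsets",
    "default_representations",
]

logger = logging.getLogger(__name__)

LIGAND_REPS = ("dft", "ecfp", "ohe")
SUBSTRATE_REPS = ("dft_fp", "smiles_fp", "ecfp", "ohe")
SPLIT_SEEDS = (0, 1, 2)
OOD_CONVERSION_THRESHOLD = 0.8
IN_DOMAIN_TEST_FRACTION = 0.2


@dataclass(frozen=True)
class CaseSpec:
    """One out-of-domain case: target substrate and its training substrates."""

    case_id: int
    target_substrate: str
    training_substrates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.target_substrate in self.training_substrates:
            raise ValueError("target substrate may not appear in training substrates")


CASES: dict[int, CaseSpec] = {
    1: CaseSpec(1, "SM3", ("SM1", "SM2")),
    2: CaseSpec(2, "SM2", ("SM1", "SM3")),
    3: CaseSpec(3, "SM1", ("SM2", "SM3")),
    4: CaseSpec(4, "SM3", ("SM1", "SM2", "SM4", "SM5")),
    5: CaseSpec(5, "SM2", ("SM1", "SM3", "SM4", "SM5")),
    6: CaseSpec(6, "SM1", ("SM2", "SM3", "SM4", "SM5")),
    7: CaseSpec(7, "SM4", ("SM3", "SM5")),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """One ML run; ``substrate_rep`` is ignored for in-domain mode."""

    mode: str  # "full_ood" | "partial_ood" | "in_domain"
    target: str  # "conversion" | "selectivity"
    ligand_rep: str
    substrate_rep: str | None = None
    case_id: int | None = None
    substrate: str | None = None
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("full_ood", "partial_ood", "in_domain"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.target not in ("conversion", "selectivity"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.mode == "in_domain":
            if self.substrate is None:
                raise ValueError("in_domain requires a substrate")
        elif self.case_id not in CASES:
            raise ValueError(f"unknown case {self.case_id!r}")


@dataclass
class HarnessConfig:
    """Grid-search space and CV folds (overridable from config files)."""

    n_estimators: tuple[int, ...] = (100, 300)
    max_depth: tuple[int | None, ...] = (3, 5, 10)
    min_samples_leaf: tuple[int, ...] = (1, 3)
    cv_folds: int = 5

    def param_grid(self, unbounded_depth: bool = False) -> dict:
        return {
            "n_estimators": list(self.n_estimators),
            # one-hot features starve under a depth cap: let those trees
            # grow until the leaves are pure
            "max_depth": [None] if unbounded_depth else list(self.max_depth),
            "min_samples_leaf": list(self.min_samples_leaf),
        }


@dataclass
class HarnessData:
    """Everything one experiment needs: outcomes plus representation tables."""

    frame: pd.DataFrame  # modeling records with ligand_id/substrate_id/conversion/ddg
    ligand_reps: dict[str, pd.DataFrame]
    substrate_reps: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class ModelResult:
    spec: ExperimentSpec
    metric_name: str
    metric: float
    per_class_recall: dict[str, float]
    importances: pd.Series
    best_params: dict
    n_train: int
    n_test: int


def modeling_frame(records: Sequence[HTERecord]) -> pd.DataFrame:
    """Records as a DataFrame with the derived ddG column (kJ/mol)."""
    frame = records_to_frame(list(records))
    frame["ddg"] = [
        ee_to_ddg(min(max(e, -0.999999), 0.999999), t)
        for e, t in zip(frame["ee"], frame["temperature"])
    ]
    return frame


def build_design_matrix(
    frame: pd.DataFrame,
    ligand_rep: pd.DataFrame,
    substrate_rep: pd.DataFrame | None,
) -> pd.DataFrame:
    """Per-record feature rows: [ligand features || substrate features].

    Column names carry provenance prefixes; a record whose id is missing
    from a representation table is an error.
    """
    missing = sorted(set(frame["ligand_id"]) - set(ligand_rep.index))
    if missing:
        raise KeyError(f"ligand ids missing from representation table: {missing[:5]}")
    lig = ligand_rep.loc[frame["ligand_id"]].reset_index(drop=True)
    lig.columns = [f"lig__{c}" for c in lig.columns]
    parts = [lig]
    if substrate_rep is not None:
        missing = sorted(set(frame["substrate_id"]) - set(substrate_rep.index))
        if missing:
            raise KeyError(f"substrate ids missing from representation table: {missing}")
        sub = substrate_rep.loc[frame["substrate_id"]].reset_index(drop=True)
        sub.columns = [f"sub__{c}" for c in sub.columns]
        parts.append(sub)
    X = pd.concat(parts, axis=1)
    X.index = frame.index
    return X


def split(frame: pd.DataFrame, spec: ExperimentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Train/test row indices for one experiment.

    Catalysts of the target substrate never straddle the boundary: fully
    out-of-domain holds out every target row, partially out-of-domain moves
    a seed-deterministic half of the target catalysts into training, and
    in-domain splits catalysts 80:20 (test size = ceil(0.2 n)).
    """
    rng = np.random.default_rng(spec.split_seed)
    if spec.mode == "in_domain":
        rows = frame.index[frame["substrate_id"] == spec.substrate].to_numpy()
        ligs = np.array(sorted(frame.loc[rows, "ligand_id"].unique()))
        perm = rng.permutation(len(ligs))
        n_test = math.ceil(IN_DOMAIN_TEST_FRACTION * len(ligs))
        test_ligs = set(ligs[perm[:n_test]])
        test = np.array([r for r in rows if frame.at[r, "ligand_id"] in test_ligs])
        train = np.array([r for r in rows if frame.at[r, "ligand_id"] not in test_ligs])
    else:
        case = CASES[spec.case_id]
        train_rows = frame.index[
            frame["substrate_id"].isin(case.training_substrates)
        ].to_numpy()
        target_rows = frame.index[frame["substrate_id"] == case.target_substrate].to_numpy()
        if spec.mode == "full_ood":
            train, test = train_rows, target_rows
        else:
            ligs = np.array(sorted(frame.loc[target_rows, "ligand_id"].unique()))
            perm = rng.permutation(len(ligs))
            half = len(ligs) // 2
            train_ligs = set(ligs[perm[:half]])
            extra = np.array(
                [r for r in target_rows if frame.at[r, "ligand_id"] in train_ligs]
            )
            test = np.array(
                [r for r in target_rows if frame.at[r, "ligand_id"] not in train_ligs]
            )
            train = np.concatenate([train_rows, extra])
    target_sub = spec.substrate if spec.mode == "in_domain" else CASES[spec.case_id].target_substrate
    train_target_ligs = set(
        frame.loc[[r for r in train if frame.at[r, "substrate_id"] == target_sub], "ligand_id"]
    )
    test_ligs_ = set(frame.loc[test, "ligand_id"])
    assert not (train_target_ligs & test_ligs_), (
        "target-substrate catalyst appears in both train and test"
    )
    return train, test


def balanced_accuracy(y_true: Iterable, y_pred: Iterable) -> float:
    """Mean of the per-class recalls."""
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    recalls = []
    for cls in np.unique(y_true):
        mask = y_true == cls
        recalls.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(recalls))


def _targets(frame: pd.DataFrame, spec: ExperimentSpec) -> pd.Series:
    if spec.target == "selectivity":
        return frame["ddg"]
    if spec.mode == "in_domain":
        # per-substrate median threshold balances the classes
        thresholds = frame.groupby("substrate_id")["conversion"].median()
        cut = frame["substrate_id"].map(thresholds)
        return (frame["conversion"] >= cut).astype(int)
    return (frame["conversion"] >= OOD_CONVERSION_THRESHOLD).astype(int)


def run_experiment(
    spec: ExperimentSpec,
    data: HarnessData,
    config: HarnessConfig | None = None,
) -> ModelResult:
    """Grid-searched random forest for one experiment spec.

    Classification scores balanced accuracy, regression R^2, both under
    k-fold CV on the training rows; importances are impurity-based and
    normalized to sum to one.
    """
    config = config or HarnessConfig()
    frame = data.frame
    substrate_rep = None
    if spec.mode != "in_domain":
        if spec.substrate_rep is None:
            raise ValueError("out-of-domain experiments need a substrate representation")
        substrate_rep = data.substrate_reps[spec.substrate_rep]
    X = build_design_matrix(frame, data.ligand_reps[spec.ligand_rep], substrate_rep)
    y = _targets(frame, spec)
    train, test = split(frame, spec)

    classification = spec.target == "conversion"
    if classification and y.loc[train].nunique() < 2:
        raise ValueError("degenerate classification task: single-class training target")

    if classification:
        estimator = RandomForestClassifier(random_state=spec.split_seed)
        scoring = "balanced_accuracy"
    else:
        estimator = RandomForestRegressor(random_state=spec.split_seed)
        scoring = "r2"
    search = GridSearchCV(
        estimator,
        config.param_grid(unbounded_depth=spec.ligand_rep == "ohe"),
        scoring=scoring,
        cv=KFold(config.cv_folds, shuffle=True, random_state=spec.split_seed),
    )
    search.fit(X.loc[train], y.loc[train])
    model = search.best_estimator_
    y_pred = model.predict(X.loc[test])

    per_class: dict[str, float] = {}
    if classification:
        metric = balanced_accuracy(y.loc[test], y_pred)
        metric_name = "BA"
        y_test = y.loc[test].to_numpy()
        for cls in np.unique(y_test):
            mask = y_test == cls
            per_class[str(cls)] = float(np.mean(y_pred[mask] == cls))
    else:
        metric = float(model.score(X.loc[test], y.loc[test]))
        metric_name = "R2"

    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    importances = pd.Series(imp, index=X.columns)
    return ModelResult(
        spec=spec,
        metric_name=metric_name,
        metric=float(metric),
        per_class_recall=per_class,
        importances=importances,
        best_params=dict(search.best_params_),
        n_train=len(train),
        n_test=len(test),
    )


def enumerate_experiments(mode: str) -> list[ExperimentSpec]:
    """The published experiment grids: 168 full-OOD, 504 partial-OOD, 90 in-domain.

    Random-descriptor controls are enumerated separately (they are controls,
    not part of the headline counts).
    """
    targets = ("conversion", "selectivity")
    specs: list[ExperimentSpec] = []
    if mode == "full_ood":
        for case_id in CASES:
            for target in targets:
                for lig in LIGAND_REPS:
                    for sub in SUBSTRATE_REPS:
                        specs.append(
                            ExperimentSpec(
                                mode="full_ood", target=target, ligand_rep=lig,
                                substrate_rep=sub, case_id=case_id,
                            )
                        )
    elif mode == "partial_ood":
        for case_id in CASES:
            for target in targets:
                for lig in LIGAND_REPS:
                    for sub in SUBSTRATE_REPS:
                        for seed in SPLIT_SEEDS:
                            specs.append(
                                ExperimentSpec(
                                    mode="partial_ood", target=target, ligand_rep=lig,
                                    substrate_rep=sub, case_id=case_id, split_seed=seed,
                                )
                            )
    elif mode == "in_domain":
        for substrate in ("SM1", "SM2", "SM3", "SM4", "SM5"):
            for target in targets:
                for lig in LIGAND_REPS:
                    for seed in SPLIT_SEEDS:
                        specs.append(
                            ExperimentSpec(
                                mode="in_domain", target=target, ligand_rep=lig,
                                substrate=substrate, split_seed=seed,
                            )
                        )
    elif mode == "random_control":
        for case_id in CASES:
            for target in targets:
                for sub in SUBSTRATE_REPS:
                    specs.append(
                        ExperimentSpec(
                            mode="full_ood", target=target, ligand_rep="random",
                            substrate_rep=sub, case_id=case_id,
                        )
                    )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return specs


def monte_carlo_subsets(
    frame: pd.DataFrame,
    features: pd.DataFrame,
    substrate: str,
    fractions: Sequence[float] = tuple(np.round(np.arange(0.9, 0.05, -0.1), 1)),
    n_splits: int = 1000,
    seed: int = 0,
    n_estimators: int = 50,
    return_membership: bool = False,
):
    """Chance-correlation study: repeated tiny-subset regressions.

    For each catalyst fraction, ``n_splits`` random subsets of that share of
    the catalyst set are drawn, each split 80:20 and fitted with a
    random-forest regressor on the descriptor features; the distribution of
    test R^2 (and its maximum) reveals how small test sets inflate the best
    observed score. Subsets too small for a nonempty train and test are
    skipped with a warning.
    """
    rows = frame.index[frame["substrate_id"] == substrate]
    sub = frame.loc[rows]
    ligs = np.array(sorted(sub["ligand_id"].unique()))
    rng = np.random.default_rng(seed)
    X_all = features.loc[sub["ligand_id"]].to_numpy()
    y_all = sub["ddg"].to_numpy()
    lig_pos = {lid: k for k, lid in enumerate(sub["ligand_id"])}
    results: dict[float, np.ndarray] = {}
    membership: list[dict] = []
    for frac in fractions:
        n_sub = int(round(frac * len(ligs)))
        n_test = math.ceil(IN_DOMAIN_TEST_FRACTION * n_sub)
        n_train = n_sub - n_test
        if n_train < 1 or n_test < 1:
            logger.warning("fraction %.2f: subset too small for a split, skipped", frac)
            continue
        scores = np.empty(n_splits)
        for s in range(n_splits):
            chosen = rng.choice(len(ligs), size=n_sub, replace=False)
            perm = rng.permutation(n_sub)
            test_ligs = ligs[chosen[perm[:n_test]]]
            train_ligs = ligs[chosen[perm[n_test:]]]
            tr = [lig_pos[l] for l in train_ligs]
            te = [lig_pos[l] for l in test_ligs]
            model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
            model.fit(X_all[tr], y_all[tr])
            scores[s] = model.score(X_all[te], y_all[te])
            if return_membership:
                membership.append(
                    {"fraction": frac, "split": s,
                     "train": list(train_ligs), "test": list(test_ligs)}
                )
        results[float(frac)] = scores
    summary = pd.DataFrame(
        {
            "fraction": list(results),
            "n_splits": [len(v) for v in results.values()],
            "median_r2": [float(np.median(v)) for v in results.values()],
            "max_r2": [float(np.max(v)) for v in results.values()],
        }
    )
    if return_membership:
        return results, summary, membership
    return results, summary


def default_representations(
    n_ligands: int = 192,
    seed: int = 0,
    descriptor_table: pd.DataFrame | None = None,
    include_random: bool = True,
    include_substrates: bool = True,
    ecfp_bits: int = 512,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Assemble the standard ligand/substrate representation tables.

    Ligands: 'dft' (34 descriptors), 'ecfp' (512-bit Morgan of the toy
    ligand SMILES), 'ohe' and optionally 'random'. Substrates: 'dft_fp'
    (steric fingerprint of the relaxed embedded geometry), 'smiles_fp'
    (same from the raw embedding), 'ecfp' and 'ohe'.
    """
    from .representations import circular_fingerprint, one_hot, random_descriptors
    from .substrates import embed_from_smiles, locate_olefin, substrate_fingerprint
    from .synthetic import SUBSTRATE_SMILES, generate_descriptor_table, ligand_ids, ligand_smiles

    lids = ligand_ids(n_ligands)
    if descriptor_table is None:
        descriptor_table = generate_descriptor_table(n_ligands, seed=seed)
    smiles = ligand_smiles(n_ligands)
    ecfp = pd.DataFrame(
        [circular_fingerprint(smiles[l], n_bits=ecfp_bits) for l in lids],
        index=pd.Index(lids, name="ligand_id"),
        columns=[f"bit_{k}" for k in range(ecfp_bits)],
    )
    ohe = one_hot(lids)
    ohe.index = pd.Index(lids, name="ligand_id")
    ligand_reps = {"dft": descriptor_table, "ecfp": ecfp, "ohe": ohe}
    if include_random:
        rand = random_descriptors(lids, seed=seed)
        rand.index.name = "ligand_id"
        ligand_reps["random"] = rand

    substrate_reps: dict[str, pd.DataFrame] = {}
    if include_substrates:
        sids = list(SUBSTRATE_SMILES)
        fp_rows, fp_raw_rows = [], []
        for sid in sids:
            smi = SUBSTRATE_SMILES[sid]
            for rows, optimize in ((fp_rows, True), (fp_raw_rows, False)):
                structure = embed_from_smiles(smi, seed=seed, optimize=optimize)
                site = locate_olefin(structure)
                fp = substrate_fingerprint(structure, site)
                rows.append(fp.as_series(name=sid))
        substrate_reps["dft_fp"] = pd.DataFrame(fp_rows)
        substrate_reps["smiles_fp"] = pd.DataFrame(fp_raw_rows)
        substrate_reps["ecfp"] = pd.DataFrame(
            [circular_fingerprint(SUBSTRATE_SMILES[s], n_bits=ecfp_bits) for s in sids],
            index=pd.Index(sids, name="substrate_id"),
            columns=[f"bit_{k}" for k in range(ecfp_bits)],
        )
        sub_ohe = one_hot(sids)
        sub_ohe.index = pd.Index(sids, name="substrate_id")
        substrate_reps["ohe"] = sub_ohe
    return ligand_reps, substrate_reps
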