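"""Block-composition evaluation protocols and accuracy/ITR aggregation.

The two recording days contribute 12 training blocks per subject
(session 1: blocks 1-6, session 2: blocks 7-12).  The protocols here
answer how those blocks should be composed into a classifier model:

* cross-session: train on one day, test on the same day (leave-one-
  block-out) or the other day (full six-block model);
* stepwise: blocks interleaved across days in the fixed sequence
  seq = 1, 7, 2, 8, 3, 9, 4, 10, 5, 11, 6, 12 and added to the model
  one at a time, testing one held-out block;
* variants V1-V5: fixed model/test splits of seq probing minimal
  training-set compositions;
* cross-subject: a subject's session model applied to every other
  subject's data.

Accuracies are fractions internally and percentages in reports; the
information transfer rate (ITR) follows the standard selection-rate
formula with N targets and T seconds per selection (2.1 s of gaze plus
a 1.0 s gaze-shift pause).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import projected_templates, score_subband_trial
from .signal_processing import FilterBankSpec, filter_bank
from .spatial_filtering import SpatialFilterSet, build_filter_set_filtered
from .synthetic_data import Study

#: The interleaved multi-day block sequence.
SEQ: tuple[int, ...] = (1, 7, 2, 8, 3, 9, 4, 10, 5, 11, 6, 12)

SESSION1_BLOCKS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
SESSION2_BLOCKS: tuple[int, ...] = (7, 8, 9, 10, 11, 12)

#: Seconds per selection: 2.10 s of stimulation + 1.0 s gaze-shift pause.
DEFAULT_SELECTION_TIME = 3.1


@dataclass(frozen=True)
class ProtocolPlan:
    """A declarative model/test block composition.

    A plan is a list of folds; each fold trains one model from
    ``model_blocks`` and tests every block in ``test_blocks``.  The
    plan accuracy is the mean over folds (equivalently over test
    blocks, since every fold here tests exactly one block).
    """

    name: str
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    subject_pairing: str | tuple[int, int] = "same"

    def __post_init__(self) -> None:
        for model_blocks, test_blocks in self.folds:
            ids = set(model_blocks) | set(test_blocks)
            if not ids <= set(range(1, 13)):
                raise ValueError(f"block ids outside 1..12 in plan {self.name}")
            if self.subject_pairing == "same" and set(model_blocks) & set(test_blocks):
                raise ValueError(
                    f"model/test blocks overlap in same-subject plan {self.name}"
                )

    @property
    def model_blocks(self) -> tuple[int, ...]:
        seen: list[int] = []
        for mb, _ in self.folds:
            seen.extend(b for b in mb if b not in seen)
        return tuple(seen)

    @property
    def test_blocks(self) -> tuple[int, ...]:
        seen: list[int] = []
        for _, tb in self.folds:
            seen.extend(b for b in tb if b not in seen)
        return tuple(seen)


def _loo_folds(blocks: tuple[int, ...]):
    return tuple(
        (tuple(b for b in blocks if b != held), (held,)) for held in blocks
    )


def cross_session_plans() -> list[ProtocolPlan]:
    """The four session-composition plans of the cross-session table.

    Same-session cells use leave-one-block-out over the six blocks;
    cross-session cells use all six source blocks as the model and each
    of the other day's blocks as test.
    """
    return [
        ProtocolPlan("Ms1_Ds1", _loo_folds(SESSION1_BLOCKS)),
        ProtocolPlan(
            "Ms1_Ds2", tuple((SESSION1_BLOCKS, (b,)) for b in SESSION2_BLOCKS)
        ),
        ProtocolPlan(
            "Ms2_Ds1", tuple((SESSION2_BLOCKS, (b,)) for b in SESSION1_BLOCKS)
        ),
        ProtocolPlan("Ms2_Ds2", _loo_folds(SESSION2_BLOCKS)),
    ]


def stepwise_plans(test_block: int) -> list[ProtocolPlan]:
    """Eleven growing-model plans for one held-out block.

    The test block is removed from seq and the model at step s is the
    first s entries of the remaining 11-block order.
    """
    if test_block not in SEQ:
        raise ValueError(f"test_block must be one of {SEQ}")
    remaining = tuple(b for b in SEQ if b != test_block)
    return [
        ProtocolPlan(
            f"step{s:02d}_test{test_block:02d}",
            ((remaining[:s], (test_block,)),),
        )
        for s in range(1, len(remaining) + 1)
    ]


def _seq_restricted(upper: int, exclude: set[int]) -> tuple[int, ...]:
    return tuple(b for b in SEQ if b <= upper and b not in exclude)


def variant_plans() -> list[ProtocolPlan]:
    """The five fixed minimal-training variants V1-V5.

    Each variant fixes one model and averages accuracy over its test
    blocks.  V3 keeps block 11 out of the model even though only 12, 6
    and 11 are tested (the model is blocks 1-10 in seq order without
    block 6); that asymmetry is part of the protocol definition.
    """
    defs = {
        "V1": ((12,), _seq_restricted(11, set())),
        "V2": ((12, 6), _seq_restricted(11, {6})),
        "V3": ((12, 6, 11), _seq_restricted(10, {6})),
        "V4": ((12, 6, 11, 5), _seq_restricted(10, {5, 6})),
        "V5": ((12, 6, 11, 5, 10), _seq_restricted(9, {5, 6})),
    }
    return [
        ProtocolPlan(name, tuple((model, (tb,)) for tb in tests))
        for name, (tests, model) in defs.items()
    ]


# ---------------------------------------------------------------------------
# evaluation engine
# ---------------------------------------------------------------------------

class Evaluator:
    """Runs protocol plans on a study, caching filter-bank decompositions.

    Every block is sub-band decomposed once per subject; models are then
    assembled from the cached decompositions for each fold.
    """

    def __init__(
        self,
        study: Study,
        spec: FilterBankSpec | None = None,
    ) -> None:
        self.study = study
        self.spec = spec or FilterBankSpec()
        self.fs = study.config.sampling_rate
        self._subband_cache: dict[int, dict[int, np.ndarray]] = {}

    def _blocks(self, subject: int) -> dict[int, np.ndarray]:
        """Sub-band-filtered blocks of a subject, keyed by global id.

        Each entry has shape (n_subbands, n_targets, m, n).
        """
        if subject not in self._subband_cache:
            raw = self.study.subject_blocks(subject)
            self._subband_cache[subject] = {
                b: filter_bank(arr, self.spec, self.fs) for b, arr in raw.items()
            }
        return self._subband_cache[subject]

    def build_model(self, subject: int, model_blocks: tuple[int, ...]) -> SpatialFilterSet:
        """Train the ensemble model from the given blocks of a subject."""
        blocks = self._blocks(subject)
        missing = [b for b in model_blocks if b not in blocks]
        if missing:
            raise ValueError(f"subject {subject} lacks blocks {missing}")
        n_targets = next(iter(blocks.values())).shape[1]
        per_class = {
            i: np.stack(
                [blocks[b][:, i - 1] for b in model_blocks], axis=1
            )  # (bands, n_trials, m, n)
            for i in range(1, n_targets + 1)
        }
        return build_filter_set_filtered(per_class)

    def _test_block_accuracy(
        self, model: SpatialFilterSet, pt: np.ndarray, subject: int, block_id: int
    ) -> float:
        block = self._blocks(subject)[block_id]  # (bands, targets, m, n)
        n_targets = block.shape[1]
        correct = 0
        for t in range(n_targets):
            d = score_subband_trial(
                block[:, t], model, self.spec, true_class=t + 1, _proj_templates=pt
            )
            correct += int(bool(d.correct))
        return correct / n_targets

    def evaluate_plan(
        self, plan: ProtocolPlan, subject: int, test_subject: int | None = None
    ) -> dict[int, float]:
        """Per-test-block accuracy fractions of one plan for one subject.

        ``test_subject`` enables cross-subject pairing: the model comes
        from ``subject``, the test data from ``test_subject``.
        """
        test_subject = subject if test_subject is None else test_subject
        out: dict[int, float] = {}
        for model_blocks, test_blocks in plan.folds:
            model = self.build_model(subject, model_blocks)
            pt = projected_templates(model)
            for tb in test_blocks:
                out[tb] = self._test_block_accuracy(model, pt, test_subject, tb)
        return out

    def plan_accuracy(
        self, plan: ProtocolPlan, subject: int, test_subject: int | None = None
    ) -> float:
        cells = self.evaluate_plan(plan, subject, test_subject)
        return float(np.mean(list(cells.values())))


def cross_subject_grid(
    session_pair: tuple[int, int],
    study: Study,
    spec: FilterBankSpec | None = None,
    evaluator: Evaluator | None = None,
) -> np.ndarray:
    """Accuracy grid of every subject's session model on every subject.

    ``session_pair`` is (model session, data session).  Cell (i, j) is
    the mean accuracy of subject i's model on subject j's test blocks.
    Diagonal cells of a same-session pair use leave-one-block-out (as in
    the cross-session plans); every other cell trains on all six model-
    session blocks and tests all six data-session blocks.
    """
    model_ses, data_ses = session_pair
    if model_ses not in (1, 2) or data_ses not in (1, 2):
        raise ValueError("sessions must be 1 or 2")
    ev = evaluator or Evaluator(study, spec)
    subjects = study.subjects
    channels = {study.tensor(s, model_ses).n_channels for s in subjects}
    if len(channels) != 1:
        raise ValueError("subjects disagree on channel count")
    model_blocks = SESSION1_BLOCKS if model_ses == 1 else SESSION2_BLOCKS
    data_blocks = SESSION1_BLOCKS if data_ses == 1 else SESSION2_BLOCKS
    full_plan = ProtocolPlan(
        f"Ms{model_ses}_Ds{data_ses}_x",
        tuple((model_blocks, (b,)) for b in data_blocks),
        subject_pairing="cross",
    )
    diag_plan = cross_session_plans()[
        {(1, 1): 0, (1, 2): 1, (2, 1): 2, (2, 2): 3}[session_pair]
    ]
    n = len(subjects)
    grid = np.empty((n, n))
    for a, si in enumerate(subjects):
        for b, sj in enumerate(subjects):
            plan = diag_plan if si == sj else full_plan
            grid[a, b] = ev.plan_accuracy(plan, si, test_subject=sj)
    return grid


# ---------------------------------------------------------------------------
# ITR and report aggregation
# ---------------------------------------------------------------------------

def itr_raw(P: float, N: int = 32, T: float = DEFAULT_SELECTION_TIME) -> float:
    """Unfloored ITR in bits/min for accuracy fraction P, N targets,
    T seconds per selection (0*log 0 taken as 0 at the endpoints)."""
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be a fraction in [0, 1]")
    if N < 2:
        raise ValueError("N must be >= 2")
    if T <= 0:
        raise ValueError("T must be > 0")
    bits = math.log2(N)
    if P > 0:
        bits += P * math.log2(P)
    if P < 1:
        bits += (1 - P) * math.log2((1 - P) / (N - 1))
    return bits * 60.0 / T


def itr(P: float, N: int = 32, T: float = DEFAULT_SELECTION_TIME) -> float:
    """ITR in bits/min, floored to 0 at or below chance (P <= 1/N).

    The raw formula turns positive again below chance; reporting those
    cells as 0 matches the convention of floored below-chance entries.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be a fraction in [0, 1]")
    if P <= 1.0 / N:
        return 0.0
    return itr_raw(P, N, T)


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy/ITR cells plus per-plan aggregates.

    ``cells`` maps (plan, subject, test block) to accuracy percent;
    ``subject_table`` is plans x subjects accuracy percent (mean over
    test blocks); ``itr_table`` the matching ITR in bits/min;
    ``aggregates`` holds the mean/SD rows of both tables.
    """

    cells: dict[tuple[str, int, int], float]
    subject_table: pd.DataFrame
    itr_table: pd.DataFrame
    aggregates: pd.DataFrame

    def __post_init__(self) -> None:
        if any(not 0.0 <= v <= 100.0 for v in self.cells.values()):
            raise ValueError("cell accuracies must be percentages in [0, 100]")


def aggregate_report(
    cells: dict[tuple[str, int, int], float],
    n_targets: int = 32,
    selection_time: float = DEFAULT_SELECTION_TIME,
) -> EvaluationReport:
    """Aggregate per-block accuracy-percent cells into a report.

    Per subject and plan the block accuracies are averaged; the mean/SD
    rows are taken across subjects (sample SD).  ITRs are computed from
    the per-subject accuracies.
    """
    if not cells:
        raise ValueError("no cells to aggregate")
    frame = pd.DataFrame(
        [(plan, subj, blk, acc) for (plan, subj, blk), acc in cells.items()],
        columns=["plan", "subject", "block", "accuracy"],
    )
    counts = frame.groupby("plan")["subject"].nunique()
    expected = sorted(frame["subject"].unique())
    incomplete = [
        p for p, c in counts.items() if c != len(expected)
    ]
    if incomplete:
        missing = {
            p: sorted(set(expected) - set(frame.loc[frame["plan"] == p, "subject"]))
            for p in incomplete
        }
        raise ValueError(f"missing cells for plans/subjects: {missing}")
    subject_table = (
        frame.groupby(["plan", "subject"])["accuracy"].mean().unstack("subject")
    )
    itr_table = subject_table.map(
        lambda p: itr(p / 100.0, n_targets, selection_time)
    )
    aggregates = pd.DataFrame(
        {
            "accuracy_mean": subject_table.mean(axis=1),
            "accuracy_sd": subject_table.std(axis=1, ddof=1),
            "itr_mean": itr_table.mean(axis=1),
            "itr_sd": itr_table.std(axis=1, ddof=1),
        }
    )
    return EvaluationReport(
        cells=dict(cells),
        subject_table=subject_table,
        itr_table=itr_table,
        aggregates=aggregates,
    )


def run_cross_session(study: Study, spec: FilterBankSpec | None = None) -> EvaluationReport:
    """Evaluate the four cross-session plans for every subject."""
    ev = Evaluator(study, spec)
    cells: dict[tuple[str, int, int], float] = {}
    for plan in cross_session_plans():
        for subj in study.subjects:
            for blk, acc in ev.evaluate_plan(plan, subj).items():
                cells[(plan.name, subj, blk)] = 100.0 * acc
    return aggregate_report(
        cells, n_targets=study.config.n_targets
    )


def run_stepwise(
    study: Study,
    spec: FilterBankSpec | None = None,
    test_blocks: tuple[int, ...] = SEQ,
    steps: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Stepwise-model accuracies, averaged over subjects.

    Returns a steps x test-blocks table of accuracy percent (the layout
    of the stepwise results table), with a final 'mean' column.
    """
    ev = Evaluator(study, spec)
    rows: dict[int, dict[int, float]] = {}
    for tb in test_blocks:
        plans = stepwise_plans(tb)
        for plan in plans:
            s = int(plan.name[4:6])
            if steps is not None and s not in steps:
                continue
            accs = [ev.plan_accuracy(plan, subj) for subj in study.subjects]
            rows.setdefault(s, {})[tb] = 100.0 * float(np.mean(accs))
    table = pd.DataFrame(rows).T.sort_index()
    table = table[[tb for tb in test_blocks if tb in table.columns]]
    table["mean"] = table.mean(axis=1)
    table.index.name = "step"
    return table


def run_variants(study: Study, spec: FilterBankSpec | None = None) -> EvaluationReport:
    """Evaluate the five minimal-training variants for every subject."""
    ev = Evaluator(study, spec)
    cells: dict[tuple[str, int, int], float] = {}
    for plan in variant_plans():
        for subj in study.subjects:
            for blk, acc in ev.evaluate_plan(plan, subj).items():
                cells[(plan.name, subj, blk)] = 100.0 * acc
    return aggregate_report(cells, n_targets=study.config.n_targets)
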