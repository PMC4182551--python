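"""Scoring ranked protein lists against essentiality labels.

Evaluation walks a ranked list from the top: at each cutoff *n*, TP(n)
counts essential proteins among the first n, FP(n) counts nonessential
ones, and proteins of unknown status occupy rank positions without
entering either count (so TP + FP <= n).  Precision is TP/(TP+FP) and
recall is TP/P, where P defaults to the number of essential-labelled
proteins under consideration in the evaluated network.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import ESSENTIAL, NONESSENTIAL, EssentialityLabels


@dataclass
class EvaluationCurve:
    """Per-cutoff evaluation points for one ranked list.

    ``frame`` has columns n, TP, FP, precision, recall; ``baseline_slope``
    is the expected TP-per-rank of a random ordering (P / N), the
    reference line for Jackknife plots.
    """

    frame: pd.DataFrame
    P: int
    baseline_slope: float

    def at(self, n: int) -> pd.Series:
        return self.frame.iloc[n - 1]


def top_k_true_positives(proteins: list[str], labels: EssentialityLabels, k: int) -> int:
    """Number of essential proteins among the first k of a ranked list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sum(1 for p in proteins[:k] if labels.status(p) == ESSENTIAL)


def _curve(proteins: list[str], labels: EssentialityLabels, P: int) -> pd.DataFrame:
    tp = fp = 0
    rows = []
    for n, p in enumerate(proteins, start=1):
        s = labels.status(p)
        if s == ESSENTIAL:
            tp += 1
        elif s == NONESSENTIAL:
            fp += 1
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rows.append((n, tp, fp, prec, tp / P))
    return pd.DataFrame(rows, columns=["n", "TP", "FP", "precision", "recall"])


def resolve_P(proteins: list[str], labels: EssentialityLabels) -> int:
    """Default P: essential-labelled proteins present in the evaluated list."""
    return sum(1 for p in proteins if labels.status(p) == ESSENTIAL)


def precision_recall(
    proteins: list[str], labels: EssentialityLabels, P: int | None = None
) -> EvaluationCurve:
    """Precision-recall curve over every prefix of the ranked list.

    ``P`` is the total number of essential proteins under consideration;
    by default the essential proteins present in the list, so a perfect
    ranking reaches recall 1.  An all-unknown prefix has precision 0.
    """
    if P is None:
        P = resolve_P(proteins, labels)
    if P < 1:
        raise ValueError("P must be >= 1")
    frame = _curve(proteins, labels, P)
    return EvaluationCurve(frame=frame, P=P, baseline_slope=P / len(proteins))


def jackknife(
    proteins: list[str], labels: EssentialityLabels, P: int | None = None
) -> EvaluationCurve:
    """Jackknife curve: cumulative TP(n) against the cutoff n.

    Also carries the random-selection reference slope P/N (a random list
    accrues essentials at that constant rate in expectation).
    """
    if P is None:
        P = resolve_P(proteins, labels)
    frame = _curve(proteins, labels, max(P, 1))
    return EvaluationCurve(frame=frame, P=P, baseline_slope=P / len(proteins))


def compare_methods(
    lists: dict[str, list[str]],
    labels: EssentialityLabels,
    ks: tuple[int, ...] = (50, 100, 200, 300, 400, 500, 600),
) -> pd.DataFrame:
    """Top-k essential counts for several methods' ranked lists.

    Returns a methods x cutoffs table of TP counts.  Lists over visibly
    different protein universes trigger a warning with the size of the
    symmetric difference (counts are then not strictly comparable).
    """
    import warnings

    universes = {name: set(lst) for name, lst in lists.items()}
    names = list(lists)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = len(universes[a] ^ universes[b])
            if diff:
                warnings.warn(
                    f"protein universes of {a!r} and {b!r} differ by {diff} proteins",
                    stacklevel=2,
                )
    rows = {
        name: {k: top_k_true_positives(lst, labels, k) for k in ks}
        for name, lst in lists.items()
    }
    out = pd.DataFrame(rows).T
    out.index.name = "method"
    return out


def plot_curves(curves: dict[str, EvaluationCurve], kind: str, path) -> None:
    """Write a simple PR or Jackknife plot (one line per method) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        if kind == "pr":
            ax.plot(curve.frame["recall"], curve.frame["precision"], label=name)
        else:
            ax.plot(curve.frame["n"], curve.frame["TP"], label=name)
    if kind == "pr":
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
    else:
        first = next(iter(curves.values()))
        nmax = first.frame["n"].iloc[-1]
        ax.plot([0, nmax], [0, nmax * first.baseline_slope], "--", color="gold",
                label="random")
        ax.set_xlabel("top n")
        ax.set_ylabel("TP(n)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
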