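"""Within-subject error bars (Cousineau normalisation, Morey correction)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = ["within_subject_sem", "morey_factor"]


def morey_factor(J: int) -> float:
    """Variance correction J / (J - 1) for J within-subject conditions.

    Applied to the variances of Cousineau-normalised values before the
    square root, it makes the resulting SEMs approximate the ANOVA MSE.
    """
    if int(J) != J or J < 2:
        raise ParameterError("J must be an integer >= 2")
    return J / (J - 1.0)


def within_subject_sem(table: pd.DataFrame, subject: str = "subject",
                       condition: str = "condition", value: str = "value",
                       morey: bool = True) -> pd.Series:
    """Per-condition within-subject SEM of a long-format balanced table.

    Each subject's mean is subtracted and the grand mean added back
    (Cousineau), removing between-subject offsets; the per-condition SEM
    of the adjusted values is returned, with the Morey variance
    correction J/(J-1) applied by default.

    Raises a ``ParameterError`` naming the missing (subject, condition)
    cells if the design is incomplete.
    """
    df = table[[subject, condition, value]].copy()
    counts = df.pivot_table(index=subject, columns=condition, values=value,
                            aggfunc="count")
    missing = [(s, c) for s in counts.index for c in counts.columns
               if not counts.loc[s, c] == counts.iloc[0, 0]
               or pd.isna(counts.loc[s, c])]
    if counts.isna().any().any() or missing:
        bad = [(s, c) for s in counts.index for c in counts.columns
               if pd.isna(counts.loc[s, c])] or missing
        raise ParameterError(f"unbalanced design; problem cells: {bad}")

    grand = df[value].mean()
    subj_means = df.groupby(subject)[value].transform("mean")
    df["adjusted"] = df[value] - subj_means + grand
    g = df.groupby(condition)["adjusted"]
    sem = g.std(ddof=1) / np.sqrt(g.count())
    if morey:
        sem = sem * np.sqrt(morey_factor(counts.shape[1]))
    return sem
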