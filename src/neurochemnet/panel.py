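"""Domain vocabulary: the analyte panel, behavioral states, and the
long-form concentration table that every pipeline stage consumes.

The default panel is the eight small-molecule neurotransmitters measured
simultaneously by LC-MS/MS from mouse prefrontal cortex dialysate:
acetylcholine (ACh), adenosine (Ado), dopamine (DA), GABA, glutamate (GLU),
histamine (HA), norepinephrine (NE) and serotonin (5HT). Concentrations are
always in nM; the two behavioral states are wakefulness ("wake") and
isoflurane anesthesia ("iso").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Analyte",
    "DEFAULT_PANEL",
    "PANEL_CODES",
    "STATES",
    "ConcentrationTable",
    "FormatError",
    "IntegrityError",
    "VocabularyError",
    "ValidationError",
]


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


class IntegrityError(ValueError):
    """A table violates a structural invariant (duplicate keys, bad flags)."""


class VocabularyError(ValueError):
    """An identifier is outside the controlled vocabulary (analyte, state)."""


class ValidationError(ValueError):
    """A configuration value is out of its legal range."""


@dataclass(frozen=True)
class Analyte:
    """One measured neurotransmitter.

    ``code`` is the short identifier used in files ("5HT", not "5-HT",
    keeping codes hyphen-free for parsing safety); ``display_name`` is the
    conventional label used in figures and summaries.
    """

    code: str
    display_name: str


DEFAULT_PANEL: tuple[Analyte, ...] = (
    Analyte("ACh", "acetylcholine"),
    Analyte("Ado", "adenosine"),
    Analyte("DA", "dopamine"),
    Analyte("GABA", "GABA"),
    Analyte("GLU", "glutamate"),
    Analyte("HA", "histamine"),
    Analyte("NE", "norepinephrine"),
    Analyte("5HT", "serotonin"),
)

PANEL_CODES: tuple[str, ...] = tuple(a.code for a in DEFAULT_PANEL)

#: The two behavioral states. Serialized exactly as these strings.
STATES: tuple[str, str] = ("wake", "iso")

#: Columns of the long-form concentration CSV, in order.
TABLE_COLUMNS = (
    "mouse_id",
    "state",
    "sample_index",
    "analyte",
    "concentration_nM",
    "below_lloq",
    "imputed",
)

REQUIRED_COLUMNS = TABLE_COLUMNS[:6]  # ``imputed`` is optional on input


@dataclass
class ConcentrationTable:
    """Long-form panel of per-(mouse, sample, analyte) concentrations.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``mouse_id`` (str), ``state`` ("wake"/"iso"),
        ``sample_index`` (int, 1-based), ``analyte`` (panel code),
        ``concentration_nM`` (float, NaN iff censored and not imputed),
        ``below_lloq`` (bool), ``imputed`` (bool).
    panel : tuple of str
        Analyte codes; every ``analyte`` value must be drawn from it.
    """

    df: pd.DataFrame
    panel: tuple[str, ...] = PANEL_CODES

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        if "imputed" not in df.columns:
            df = df.copy()
            df["imputed"] = False
            self.df = df

        bad_state = set(df["state"].unique()) - set(STATES)
        if bad_state:
            raise VocabularyError(
                f"unknown state label(s) {sorted(bad_state)}; expected {STATES}"
            )
        bad_analyte = set(df["analyte"].unique()) - set(self.panel)
        if bad_analyte:
            raise VocabularyError(
                f"unknown analyte code(s) {sorted(bad_analyte)}; panel is {self.panel}"
            )

        keys = df[["mouse_id", "sample_index", "analyte"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise IntegrityError(f"duplicate (mouse_id, sample_index, analyte) key: {dup}")

        states_per_mouse = df.groupby("mouse_id")["state"].nunique()
        if (states_per_mouse > 1).any():
            mouse = states_per_mouse[states_per_mouse > 1].index[0]
            raise IntegrityError(f"mouse {mouse!r} appears under more than one state")

        absent = df["concentration_nM"].isna()
        if (absent & ~df["below_lloq"].astype(bool)).any():
            raise IntegrityError(
                "absent concentration with below_lloq=False: only LLOQ-censored "
                "values may be missing"
            )
        if (absent & df["imputed"].astype(bool)).any():
            raise IntegrityError("imputed records must carry a concentration")
        conc = df["concentration_nM"]
        if (conc.dropna() < 0).any():
            raise IntegrityError("negative concentration_nM")

    # -- convenience --------------------------------------------------
    @property
    def design(self) -> tuple[int, int, int]:
        """(n_wake, n_iso, samples_per_mouse) inferred from the records."""
        mice = self.df.drop_duplicates("mouse_id")
        n_wake = int((mice["state"] == "wake").sum())
        n_iso = int((mice["state"] == "iso").sum())
        return n_wake, n_iso, int(self.df["sample_index"].max())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def mice(self, state: str | None = None) -> list[str]:
        df = self.df if state is None else self.df[self.df["state"] == state]
        return sorted(df["mouse_id"].unique())

    def is_complete(self) -> bool:
        """True if no concentration is absent (after imputation)."""
        return not self.df["concentration_nM"].isna().any()

    def copy(self) -> "ConcentrationTable":
        return ConcentrationTable(self.df.copy(), self.panel)

    def sorted(self) -> "ConcentrationTable":
        df = (
            self.df.sort_values(["state", "mouse_id", "sample_index", "analyte"])
            .reset_index(drop=True)
        )
        return ConcentrationTable(df, self.panel)

    def equals(self, other: "ConcentrationTable") -> bool:
        a = self.sorted().df.reset_index(drop=True)
        b = other.sorted().df.reset_index(drop=True)
        if self.panel != other.panel or len(a) != len(b):
            return False
        a = a[list(TABLE_COLUMNS)]
        b = b[list(TABLE_COLUMNS)]
        same = True
        for col in TABLE_COLUMNS:
            if col == "concentration_nM":
                same &= np.allclose(
                    a[col].to_numpy(float), b[col].to_numpy(float), equal_nan=True, rtol=0, atol=0
                )
            else:
                same &= bool((a[col].to_numpy() == b[col].to_numpy()).all())
        return same
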