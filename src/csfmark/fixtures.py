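"""Packaged reference tables from the published two-phase CSF study.

Four small TSVs ship with the package: the 61-sample cohort demographics,
the 53-protein discovery differential table, the 56-peptide PRM target
panel with response-curve linear ranges, and the 29 peptide-level
significance calls from the validation phase. Loaders validate the column
schema and expose the derived counts the pipeline relies on.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_SCHEMAS = {
    "table1_demographics.tsv": [
        "subject_id", "sample_type", "group", "alsfrs", "sex", "race",
        "age", "application",
    ],
    "table2_differential.tsv": [
        "protein_name", "gene_symbol", "p_value", "q_value", "log2fc",
        "detectable_by_prm", "q_band",
    ],
    "peptide_panel.tsv": [
        "gene_symbol", "peptide", "linear_low_fmol", "linear_high_fmol",
    ],
    "validation_calls.tsv": [
        "gene_symbol", "peptide", "direction", "peptide_ambiguous",
    ],
}


@dataclass
class PaperFixtures:
    table1: pd.DataFrame
    table2: pd.DataFrame
    peptide_panel: pd.DataFrame
    validation_calls: pd.DataFrame

    def counts(self) -> dict[str, int]:
        """The headline counts of the study design."""
        t2 = self.table2
        calls = self.validation_calls
        return {
            "differential_proteins": len(t2),
            "q_lt_0.05": int((t2["q_value"] < 0.05).sum()),
            "q_lt_0.1": int((t2["q_value"] < 0.1).sum()),
            "detectable_by_prm": int(t2["detectable_by_prm"].sum()),
            "validation_samples": len(self.table1),
            "validation_als": int((self.table1["group"] == "ALS").sum()),
            "validation_hc": int((self.table1["group"] == "HC").sum()),
            "discovery_samples": int(
                self.table1["application"].str.contains("Discovery").sum()
            ),
            "panel_peptides": len(self.peptide_panel),
            "panel_proteins": int(self.peptide_panel["gene_symbol"].nunique()),
            "significant_peptides": len(calls),
            "significant_up": int((calls["direction"] == "up").sum()),
            "significant_down": int((calls["direction"] == "down").sum()),
        }


def _read(name: str) -> pd.DataFrame:
    path = resources.files("csfmark.data") / name
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    expected = _SCHEMAS[name]
    for col in expected:
        if col not in df.columns:
            raise ValueError(f"{name}: missing column {col!r}")
    return df


def load_paper_fixtures() -> PaperFixtures:
    """Load and validate all packaged reference tables."""
    table1 = _read("table1_demographics.tsv")
    table2 = _read("table2_differential.tsv")
    panel = _read("peptide_panel.tsv")
    calls = _read("validation_calls.tsv")
    table2["detectable_by_prm"] = table2["detectable_by_prm"].astype(bool)
    calls["peptide_ambiguous"] = calls["peptide_ambiguous"].astype(bool)
    missing = set(calls["peptide"]) - set(panel["peptide"])
    if missing:
        raise ValueError(f"validation calls not in the peptide panel: {missing}")
    return PaperFixtures(
        table1=table1, table2=table2, peptide_panel=panel, validation_calls=calls
    )
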