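import numpy as np
import pandas as pd
import pytest

from midna.io import LipidDataset, MissingCode


def build_dataset(values, code=None, lloq=None, group=None, covariates=None, scale="log"):
    """Assemble a LipidDataset from plain arrays (NaN-ing non-observed cells)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if code is None:
        code = np.zeros((n, p), dtype=np.int8)
    code = np.asarray(code, dtype=np.int8)
    vals = values.copy()
    vals[code != int(MissingCode.OBSERVED)] = np.nan
    patients = [f"P{i}" for i in range(n)]
    analytes = [f"L{j + 1}" for j in range(p)]
    if lloq is None:
        lloq = np.full(p, np.nan)
    if group is None:
        group = ["case"] * (n // 2) + ["control"] * (n - n // 2)
    if covariates is None:
        covariates = pd.DataFrame(index=patients)
    else:
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float), index=patients)
    return LipidDataset(
        values=pd.DataFrame(vals, index=patients, columns=analytes),
        missing_code=pd.DataFrame(code, index=patients, columns=analytes),
        lloq=pd.Series(np.asarray(lloq, dtype=float), index=analytes),
        group=pd.Series(list(group), index=patients),
        covariates=covariates,
        scale=scale,
    )


@pytest.fixture
def make_dataset():
    return build_dataset


@pytest.fixture
def toy_csvs(tmp_path):
    """3-patient, 2-analyte CSV triple with one blank (censored) cell."""

    def write(shuffle=False, drop_lloq=False, codes=False):
        rows = [
            ("A", 1.2, 3.0),
            ("B", "", 2.5),
            ("C", 0.8, 4.1),
        ]
        if shuffle:
            rows = [rows[2], rows[0], rows[1]]
        values = tmp_path / "values.csv"
        values.write_text(
            "patient_id,L1,L2\n" + "\n".join(f"{r[0]},{r[1]},{r[2]}" for r in rows) + "\n"
        )
        lloq = tmp_path / "lloq.csv"
        if drop_lloq:
            lloq.write_text("analyte_id,lloq\nL2,0.5\n")
        else:
            lloq.write_text("analyte_id,lloq\nL1,0.9\nL2,0.5\n")
        cov_rows = [("A", "case", 60), ("B", "control", 55), ("C", "case", 70)]
        cov = tmp_path / "covariates.csv"
        cov.write_text(
            "patient_id,group,age\n" + "\n".join(f"{r[0]},{r[1]},{r[2]}" for r in cov_rows) + "\n"
        )
        paths = dict(values=values, lloq=lloq, covariates=cov, codes=None)
        if codes:  # flag the blank cell explicitly: "mcar" or "censored"
            letter = {"mcar": "M", "censored": "C"}[codes]
            codes_file = tmp_path / "codes.csv"
            codes_file.write_text(f"patient_id,L1,L2\nA,O,O\nB,{letter},O\nC,O,O\n")
            paths["codes"] = codes_file
        return paths

    return write
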