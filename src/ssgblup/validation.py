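"""Forward-validation protocol for genomic evaluations.

A partial dataset removes the phenotypes of a chosen validation group and
resets, in the pedigree, the links between validated animals and their
descendants (the validated animal is blanked out of its progeny's sire/dam
slots; the progeny records themselves stay). Early predictions from the
partial data — parent averages, ssGBLUP or wssGBLUP GEBV — are then compared
against whole-data estimates (or simulated truth) with Pearson correlation
and the dispersion (inflation) regression final = b0 + b * prediction, whose
slope b is 1 for unbiased dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mme import TraitDataset
from .pedigree import UNKNOWN, Pedigree


class ValidationError(ValueError):
    pass


@dataclass
class ValidationScenario:
    validated_ids: list[str]
    partial_data: TraitDataset
    partial_pedigree: Pedigree
    reference_ids: Optional[list[str]] = None  # genotyped reference group


def make_partial_dataset(data: TraitDataset, pedigree: Pedigree,
                         validated_ids: Sequence[str],
                         reference_ids: Optional[Sequence[str]] = None) -> ValidationScenario:
    """Delete validated animals' phenotypes and unlink them from their progeny.

    Validated animals must exist in the pedigree and have a phenotype record.
    Genotypes are untouched: a validated animal stays in the reference group
    (its phenotype, not its genotype, is hidden).
    """
    validated = [str(v) for v in validated_ids]
    vset = set(validated)
    phenotyped = set(data.animal_ids)
    for v in validated:
        if v not in pedigree.id_index:
            raise ValidationError(f"validated animal {v!r} not in pedigree")
        if v not in phenotyped:
            raise ValidationError(f"validated animal {v!r} has no phenotype record")

    keep = [a not in vset for a in data.animal_ids]
    partial = TraitDataset(data.data.loc[keep].reset_index(drop=True), data.id_col)

    vpos = set(pedigree.positions(validated).tolist())
    sire = pedigree.sire.copy()
    dam = pedigree.dam.copy()
    sire[np.isin(sire, list(vpos))] = UNKNOWN
    dam[np.isin(dam, list(vpos))] = UNKNOWN
    ped = Pedigree(list(pedigree.ids), sire, dam)
    return ValidationScenario(validated, partial, ped,
                              list(reference_ids) if reference_ids is not None else None)


def validation_metrics(predictions: pd.Series, finals: pd.Series) -> dict:
    """Pearson r plus the inflation regression final = b0 + b*prediction.

    Inputs are aligned on their (animal-id) index; at least three paired
    values with variation in both vectors are required.
    """
    ids = predictions.index.intersection(finals.index)
    x = predictions.loc[ids].to_numpy(dtype=float)
    y = finals.loc[ids].to_numpy(dtype=float)
    if len(ids) < 3:
        raise ValidationError(f"need >= 3 paired values, got {len(ids)}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValidationError("zero variance in predictions or finals")
    fit = stats.linregress(x, y)
    return {
        "n": int(len(ids)),
        "r": float(fit.rvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue ** 2),
        "bias": float(np.mean(y - x)),
    }


def validation_report(predictions: Mapping[str, pd.Series],
                      finals: Mapping[str, pd.Series],
                      validated_ids: Sequence[str]) -> pd.DataFrame:
    """Table of r / slope / R^2 for every (final, prediction) pair.

    Mirrors the layout final-estimate rows x prediction columns, restricted
    to the validated animals.
    """
    ids = [str(v) for v in validated_ids]
    rows = []
    for fname, fvals in finals.items():
        for pname, pvals in predictions.items():
            m = validation_metrics(pvals.loc[ids], fvals.loc[ids])
            rows.append({"final": fname, "prediction": pname, **m})
    return pd.DataFrame(rows)


def scenario_compare(results: Mapping[str, Mapping[str, np.ndarray]]) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-animal and per-SNP summaries.

    ``results`` maps scenario name -> {"u": aligned EBV/GEBV vector,
    "variance_share": per-SNP shares, "weights": per-SNP weights}; any subset
    of those keys is allowed but orders must be aligned across scenarios.
    Degenerate (zero-variance) vectors yield a not-applicable (NaN) entry
    rather than an error.
    """
    names = list(results)
    if len(names) < 2:
        raise ValidationError("scenario comparison needs >= 2 scenarios")
    quantities = sorted({k for r in results.values() for k in r})
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            row = {"scenario_a": a, "scenario_b": b}
            for qn in quantities:
                va, vb = results[a].get(qn), results[b].get(qn)
                if va is None or vb is None:
                    row[qn] = np.nan
                    continue
                va = np.asarray(va, float)
                vb = np.asarray(vb, float)
                if va.shape != vb.shape:
                    raise ValidationError(
                        f"misaligned {qn!r} vectors between scenarios {a!r} and {b!r}")
                if np.std(va) == 0.0 or np.std(vb) == 0.0:
                    row[qn] = np.nan  # not applicable: constant vector
                else:
                    row[qn] = float(np.corrcoef(va, vb)[0, 1])
            rows.append(row)
    return pd.DataFrame(rows)
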