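"""Individual precision mapping.

A fitted group atlas can be tailored to a single person by Bayes rule: the
individual posterior is the (voxel-wise, renormalized) product of the group
prior from the arrangement model and the likelihood of the person's
localizer data under the dataset-specific emission model. Three map sources
are distinguished:

``group``
    the arrangement model alone — what you would use with no individual data;
``data_only``
    the emission likelihood alone — a purely individual map;
``integrated``
    the Bayes combination of the two.

With little localizer data the integrated map leans on the group prior;
with much reliable data it converges to the data-only map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import FunctionalDataset
from .emission import PreparedSubject, VmfEmission, prepare_dataset
from .fusion import FusedModel


@dataclass
class IndividualParcellation:
    posterior: np.ndarray  # (K, P), columns sum to 1
    hard_labels: np.ndarray  # (P,) argmax, ties to the lowest parcel index
    source: str  # group | data_only | integrated
    minutes_of_data: float = 0.0

    @classmethod
    def from_posterior(cls, posterior, source, minutes_of_data=0.0):
        posterior = np.asarray(posterior, dtype=float)
        return cls(
            posterior=posterior,
            hard_labels=np.argmax(posterior, axis=0),
            source=source,
            minutes_of_data=minutes_of_data,
        )


def group_map(model: FusedModel) -> IndividualParcellation:
    """The group parcellation, from the arrangement model only."""
    return IndividualParcellation.from_posterior(model.group_prob(), "group")


def individual_map(
    model: FusedModel,
    emission: VmfEmission,
    subject: PreparedSubject,
    mode: str = "integrated",
    minutes_of_data: float = 0.0,
) -> IndividualParcellation:
    """Individual parcellation from one subject's localizer data.

    ``data_only``: posterior proportional to exp(emission log-likelihood);
    ``integrated``: posterior proportional to exp(emission log-lik + eta),
    i.e. the normalized product of group prior and likelihood.
    """
    if mode not in ("data_only", "integrated"):
        raise ValueError(f"unknown mode {mode!r}")
    logp = emission.log_prob(subject)
    if mode == "integrated":
        logp = logp + model.arrangement.log_prob()
    post = np.exp(logp - logsumexp(logp, axis=0, keepdims=True))
    return IndividualParcellation.from_posterior(post, mode, minutes_of_data)


def train_localizer_emission(
    model: FusedModel,
    new_dataset: FunctionalDataset,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> VmfEmission:
    """Fit a new dataset-specific emission model with the arrangement frozen.

    Used when individual localizer tasks differ from every training task
    set: EM runs over the new emission only, pooling all the new dataset's
    subjects. Initialization is the constant-direction emission, whose first
    E-step posterior equals the group prior exactly — deterministic, and it
    anchors the new parcels to the atlas labels. The arrangement is never
    touched.
    """
    prepared = prepare_dataset(new_dataset)
    sizes = [len(c) for c in new_dataset.average_runs().session_partition()]
    emi = VmfEmission(model.K, sizes)
    log_prior = model.arrangement.log_prob()
    prev_ll = -np.inf
    for _ in range(max_iter):
        posteriors = []
        ll = 0.0
        for subj in prepared:
            logp = emi.log_prob(subj) + log_prior
            lse = logsumexp(logp, axis=0)
            posteriors.append(np.exp(logp - lse[None, :]))
            ll += float(lse.sum())
        emi.m_step(posteriors, prepared)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
    return emi


def maps_for_dataset(
    model: FusedModel,
    emission: VmfEmission,
    dataset: FunctionalDataset,
    mode: str,
    minutes_of_data: float = 0.0,
) -> list[IndividualParcellation]:
    prepared = prepare_dataset(dataset)
    if mode == "group":
        return [group_map(model) for _ in prepared]
    return [
        individual_map(model, emission, subj, mode, minutes_of_data) for subj in prepared
    ]


def data_amount_curve(
    model: FusedModel,
    dataset: FunctionalDataset,
    amounts: list[int],
    space,
    binning=None,
    run_minutes: float = 1.0,
) -> pd.DataFrame:
    """Individual-map quality as a function of localizer data amount.

    The dataset's runs are split in half: the first half plays the localizer
    role, the second is held out for scoring. A localizer emission model is
    trained (arrangement frozen) on the full first half across subjects;
    then, for every requested run count, each subject's maps are derived
    from that many localizer runs and scored on the held-out half with DCBC
    and weighted cosine prediction error. Returns a tidy table with columns
    amount, minutes, source, subject, dcbc, prediction_error.
    """
    from .metrics import DistanceBinning, dcbc, prediction_error, profile_matrix

    if binning is None:
        binning = DistanceBinning(space)
    train, test = dataset.split_half_by_runs()
    emission = train_localizer_emission(model, train)
    prepared_test = prepare_dataset(test)
    test_avg = test.average_runs()
    n_subj = dataset.n_subjects

    rows = []
    for amount in amounts:
        runs = train.runs()[:amount]
        if len(runs) < amount:
            raise ValueError(f"dataset has only {len(runs)} localizer runs")
        sub = train.select_runs(runs)
        prep_loc = prepare_dataset(sub)
        for source in ("group", "data_only", "integrated"):
            maps = (
                [group_map(model) for _ in range(n_subj)]
                if source == "group"
                else [
                    individual_map(model, emission, subj, source)
                    for subj in prep_loc
                ]
            )
            for s in range(n_subj):
                labels = maps[s].hard_labels
                score = dcbc(labels, profile_matrix(prepared_test[s]), space, binning)
                others = [t for t in range(n_subj) if t != s]
                err = prediction_error(
                    labels,
                    [test_avg.data[t] for t in others],
                    test_avg.data[s],
                    train_labels=[maps[t].hard_labels for t in others],
                )
                rows.append(
                    {
                        "amount": amount,
                        "minutes": amount * run_minutes,
                        "source": source,
                        "subject": dataset.subjects[s],
                        "dcbc": score,
                        "prediction_error": err,
                    }
                )
    return pd.DataFrame(rows)
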