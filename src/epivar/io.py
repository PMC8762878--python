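"""Delimited-text readers and writers for pipeline artefacts.

All on-disk formats are plain text: marker matrices and manifests as
TSV, posterior draws as a directory of TSV tables plus a JSON manifest
recording dimensions and seeds so a reload is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MarkerMatrix, PosteriorDraws


def read_marker_matrix(values_path, manifest_path, standardized: bool = False) -> MarkerMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"chr": str})
    return MarkerMatrix(values, manifest, standardized=standardized)


def write_marker_matrix(markers: MarkerMatrix, values_path, manifest_path) -> None:
    markers.values.to_csv(values_path, sep="\t")
    markers.manifest.to_csv(manifest_path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_draws(draws: PosteriorDraws, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "beta.tsv", draws.beta, delimiter="\t", fmt="%.17g")
    np.savetxt(out / "components.tsv", draws.components, delimiter="\t", fmt="%d")
    np.savetxt(out / "sigma2_g.tsv", draws.sigma2_g, delimiter="\t", fmt="%.17g")
    np.savetxt(out / "sigma2_e.tsv", draws.sigma2_e, delimiter="\t", fmt="%.17g")
    np.savetxt(
        out / "pi.tsv", draws.pi.reshape(draws.n_draws, -1), delimiter="\t", fmt="%.17g"
    )
    np.savetxt(out / "chain.tsv", draws.chain, delimiter="\t", fmt="%d")
    manifest = {
        "marker_ids": list(map(str, draws.marker_ids)),
        "set_labels": list(draws.set_labels),
        "set_index": [int(s) for s in draws.set_index],
        "n_draws": int(draws.n_draws),
        "n_components": int(draws.pi.shape[2]),
        "standardized_input": bool(draws.standardized_input),
    }
    (out / "draws.json").write_text(json.dumps(manifest, indent=1))


def read_draws(in_dir) -> PosteriorDraws:
    src = Path(in_dir)
    manifest = json.loads((src / "draws.json").read_text())
    n_draws = manifest["n_draws"]
    n_sets = len(manifest["set_labels"])
    kc = manifest["n_components"]
    return PosteriorDraws(
        beta=np.loadtxt(src / "beta.tsv", delimiter="\t", ndmin=2),
        components=np.loadtxt(src / "components.tsv", delimiter="\t", ndmin=2).astype(np.int8),
        sigma2_g=np.loadtxt(src / "sigma2_g.tsv", delimiter="\t", ndmin=2),
        sigma2_e=np.loadtxt(src / "sigma2_e.tsv", delimiter="\t", ndmin=1),
        pi=np.loadtxt(src / "pi.tsv", delimiter="\t", ndmin=2).reshape(n_draws, n_sets, kc),
        chain=np.loadtxt(src / "chain.tsv", delimiter="\t", ndmin=1).astype(int),
        marker_ids=manifest["marker_ids"],
        set_labels=manifest["set_labels"],
        set_index=np.asarray(manifest["set_index"], dtype=np.int64),
        standardized_input=manifest["standardized_input"],
    )


def write_weights(weights, path) -> None:
    weights.weights.to_frame().to_csv(path, sep="\t")


def read_weights(path, set_label: str = "methylation"):
    from .episcore import EpiScoreWeights

    df = pd.read_csv(path, sep="\t", index_col=0)
    return EpiScoreWeights(
        weights=df.iloc[:, 0].rename("weight"), training_n=-1, set_label=set_label
    )
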