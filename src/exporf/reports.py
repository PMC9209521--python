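"""Result bundle writer: CSV tables plus a JSON manifest with checksums."""

from __future__ import annotations

from pathlib import Path

from .cohort import sha256_of, write_json

__all__ = ["write_report_bundle"]

FLOAT_FMT = "%.12g"


def write_report_bundle(results, out_dir) -> dict:
    """Write every pipeline artifact as CSV and return the manifest.

    Files: summary feature table (+ missing mask), tuning table, importance
    ranking, q-curve, per-feature PDP/ALE grids, evaluation table, domain
    ablation table, and manifest.json carrying the config, seed and a
    sha256 per file. Deterministic given the run seed: floats are printed
    to 12 significant digits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _write(name: str, frame) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format=FLOAT_FMT)
        files[name] = str(path)

    results.table.to_csv(out / "summary_features.csv", out / "missing_mask.csv")
    files["summary_features.csv"] = str(out / "summary_features.csv")
    files["missing_mask.csv"] = str(out / "missing_mask.csv")

    _write("tuning.csv", results.tuning.to_frame())
    _write("importance.csv", results.importance.to_frame(results.table.feature_meta))
    if len(results.q_curve.q_values):
        _write("q_curve.csv", results.q_curve.to_frame())
    _write("evaluation.csv", results.evaluation_frame())
    _write("calibration_full.csv", results.full_eval.calibration_bins)
    _write("calibration_reduced.csv", results.reduced_eval.calibration_bins)
    if results.ablation is not None:
        _write("ablation.csv", results.ablation)
    effects_dir = out / "effects"
    effects_dir.mkdir(exist_ok=True)
    for fid, pair in results.effect_curves.items():
        safe = fid.replace("/", "_")
        for kind, curve in pair.items():
            name = f"effects/{safe}.{kind}.csv"
            curve.to_frame().to_csv(out / name, index=False, float_format=FLOAT_FMT)
            files[name] = str(out / name)

    manifest = {
        "config": results.config.to_dict(),
        "seed": results.config.seed,
        "selected_q": int(results.selected_q),
        "selected_features": list(results.selected_features),
        "files": {name: sha256_of(path) for name, path in sorted(files.items())},
    }
    write_json(manifest, out / "manifest.json")
    return manifest
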