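"""Shared paths and demo bootstrap for the numbered analysis scripts."""

from pathlib import Path

from chromguide.pipeline import RunConfig, make_demo

ROOT = Path(__file__).resolve().parent.parent
DEMO_DIR = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"
SEED = 1


def ensure_demo() -> RunConfig:
    """Build the synthetic demo dataset once; reuse it across scripts."""
    RESULTS.mkdir(exist_ok=True)
    config_path = DEMO_DIR / "config.yaml"
    if not config_path.exists():
        make_demo(DEMO_DIR, seed=SEED)
    return RunConfig.load(config_path)
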