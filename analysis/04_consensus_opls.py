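"""Two-block consensus OPLS-DA per cell type: RV-weighted kernel fusion,
1 predictive + 1 orthogonal latent variable, 7-fold cross-validated Q2,
permutation significance and per-feature VIP.
"""
import json

from common import RESULTS, get_pipeline


def main() -> None:
    pipe = get_pipeline()
    pipe.run(stages=["copls"])
    summary = json.load(open(RESULTS / "copls_summary.json"))
    for ct, s in summary.items():
        lam = s["block_contributions"]
        print(
            f"{ct}: R2Y={s['r2y']:.3f} Q2={s['q2']:.3f} "
            f"perm_p={s['perm_p']:.3g} (t-test p={s['perm_t_p']:.2g}) "
            f"lambda rna/protein = {lam['rna']:.2f}/{lam['protein']:.2f}"
        )
    print(
        "note: in-sample R2Y is ~1 for n=10 samples with thousands of "
        "features; Q2 and the permutation test carry the evidence"
    )


if __name__ == "__main__":
    main()
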