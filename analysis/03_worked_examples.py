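"""Recompute the published worked-example numbers from in-table values.

These are the desk-scale checks: Cohen's f² column, demographic tests,
the held-out confusion matrix, and the 70/30 split arithmetic.

Usage: python analysis/03_worked_examples.py
"""

from mgmv.classify import split_train_test
from mgmv.outcomes import chi_square_2x2, welch_t
from mgmv.regression import cohens_f2


def main() -> None:
    print("Cohen's f2 from adjusted R2 (published column):")
    for r2 in (0.33, 0.11, 0.26, 0.18, 0.07):
        print(f"  R2_adj = {r2:.2f} -> f2 = {cohens_f2(r2):.2f}")

    t, df, p = welch_t(61.46, 11.11, 120, 60.18, 9.38, 88)
    print(f"\nWelch t on age (120 HC vs 88 PD): t = {t:.2f}, "
          f"df = {df:.1f}, p = {p:.2f}")
    chi2, p = chi_square_2x2(80, 40, 60, 28, correction=False)
    print(f"Pearson chi2 on sex (80:40 vs 60:28): chi2 = {chi2:.2f}, "
          f"p = {p:.2f}")

    print("\nConfusion matrices on n = 27 consistent with "
          "sensitivity 87.50% / specificity 90.91%:")
    for pos in range(1, 27):
        for tp in range(pos + 1):
            for tn in range(27 - pos + 1):
                if (round(100 * tp / pos, 2) == 87.50
                        and round(100 * tn / (27 - pos), 2) == 90.91):
                    fn, fp = pos - tp, 27 - pos - tn
                    acc = 100 * (tp + tn) / 27
                    print(f"  (tp, fn, tn, fp) = ({tp}, {fn}, {tn}, {fp})"
                          f" -> accuracy {acc:.1f}%")

    train, test = split_train_test(88, test_fraction=0.3, seed=0)
    print(f"\n70/30 split of 88 subjects -> ({len(train)}, {len(test)})")


if __name__ == "__main__":
    main()
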