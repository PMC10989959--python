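import numpy as np
import pandas as pd
import pytest

import netperturb as npb


def two_subtype_cohort(rng, n_genes=60, n_per=20, shift=5.0, sd=0.5):
    """Genes 0-9 carry a +shift in subtype A; the rest are noise."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    base = rng.uniform(2, 10, size=n_genes)
    a = base[:, None] + rng.normal(0, sd, size=(n_genes, n_per))
    a[:10] += shift
    b = base[:, None] + rng.normal(0, sd, size=(n_genes, n_per))
    cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    expr = pd.DataFrame(np.hstack([a, b]), index=genes, columns=cols)
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=cols)
    return expr, labels


class TestDeriveSignatures:
    def test_planted_markers_found(self):
        rng = np.random.default_rng(0)
        expr, labels = two_subtype_cohort(rng)
        sig = npb.derive_signatures(expr, labels, n_per_subtype=10)
        assert sorted(sig.markers["A"]) == [f"g{i:02d}" for i in range(10)]

    def test_zero_per_subtype_empty(self):
        rng = np.random.default_rng(0)
        expr, labels = two_subtype_cohort(rng)
        sig = npb.derive_signatures(expr, labels, n_per_subtype=0)
        assert all(len(v) == 0 for v in sig.markers.values())

    def test_marker_lists_disjoint_and_upregulated(self, discovery_run):
        sig = discovery_run.signatures
        all_markers = [g for m in sig.markers.values() for g in m]
        assert len(all_markers) == len(set(all_markers))
        assert (sig.stats["effect"] > 0).all()

    def test_small_subtype_errors(self):
        rng = np.random.default_rng(0)
        expr, labels = two_subtype_cohort(rng)
        labels.iloc[:] = "A"
        labels.iloc[0] = "B"
        with pytest.raises(ValueError, match="fewer than 2"):
            npb.derive_signatures(expr, labels)

    def test_signature_frame_roundtrip(self):
        rng = np.random.default_rng(1)
        expr, labels = two_subtype_cohort(rng)
        sig = npb.derive_signatures(expr, labels, n_per_subtype=5)
        again = npb.SignatureSet.from_frame(sig.to_frame())
        assert again.markers == sig.markers


class TestNtpClassify:
    def test_template_sample_has_min_p(self):
        """A sample whose standardized profile is the template itself is
        predicted with near-zero distance and the smallest attainable p."""
        rng = np.random.default_rng(2)
        expr, labels = two_subtype_cohort(rng, n_per=15)
        sig = npb.derive_signatures(expr, labels, n_per_subtype=10)
        union = sig.union
        # craft a cohort where one sample equals A's indicator over the union
        n_resample = 200
        z = pd.DataFrame(
            rng.normal(size=(len(expr.index), 20)),
            index=expr.index,
            columns=[f"s{i}" for i in range(20)],
        )
        template = pd.Series(0.0, index=expr.index)
        template.loc[sig.markers["A"]] = 1.0
        # standardize against fixed reference moments so the probe's
        # standardized profile equals the template exactly
        mean, sd = z.mean(axis=1), z.std(axis=1, ddof=0)
        z["probe"] = template * sd + mean
        res = npb.ntp_classify(
            z, sig, n_resample=n_resample, seed=3, ref_mean=mean, ref_sd=sd
        )
        probe = res.loc["probe"]
        assert probe["predicted"] == "A"
        assert probe["dist_A"] == pytest.approx(0.0, abs=1e-12)
        assert probe["pvalue"] == pytest.approx(1 / (n_resample + 1))

    def test_p_bounds(self, discovery_run):
        vexpr, _ = npb.simulate_validation_cohort(discovery_run.study, 40, seed=21)
        res = npb.ntp_classify(vexpr, discovery_run.signatures, n_resample=100, seed=4)
        assert (res["pvalue"] >= 1 / 101).all()
        assert (res["pvalue"] <= 1.0).all()
        dist_cols = [c for c in res.columns if c.startswith("dist_")]
        assert (res[dist_cols] >= 0).all().all()
        assert (res[dist_cols] <= 2).all().all()
        # predicted is the arg-min distance
        argmin = res[dist_cols].idxmin(axis=1).str.removeprefix("dist_")
        assert (argmin == res["predicted"]).all()

    def test_affine_rescaling_invariance(self, discovery_run):
        vexpr, _ = npb.simulate_validation_cohort(discovery_run.study, 30, seed=22)
        rng = np.random.default_rng(5)
        scale = pd.Series(rng.uniform(0.5, 3.0, len(vexpr.index)), index=vexpr.index)
        shift = pd.Series(rng.normal(0, 4, len(vexpr.index)), index=vexpr.index)
        r1 = npb.ntp_classify(vexpr, discovery_run.signatures, n_resample=50, seed=6)
        r2 = npb.ntp_classify(
            vexpr.mul(scale, axis=0).add(shift, axis=0),
            discovery_run.signatures, n_resample=50, seed=6,
        )
        assert (r1["predicted"] == r2["predicted"]).all()
        assert np.allclose(r1["pvalue"], r2["pvalue"])

    def test_low_coverage_errors(self, discovery_run):
        vexpr, _ = npb.simulate_validation_cohort(discovery_run.study, 10, seed=23)
        union = discovery_run.signatures.union
        keep = [g for g in vexpr.index if g not in set(union[: int(0.6 * len(union))])]
        with pytest.raises(ValueError, match="coverage"):
            npb.ntp_classify(vexpr.loc[keep], discovery_run.signatures, n_resample=20)

    def test_single_sample_needs_reference(self, discovery_run):
        vexpr, _ = npb.simulate_validation_cohort(discovery_run.study, 30, seed=24)
        with pytest.raises(ValueError, match="single-sample"):
            npb.ntp_classify(vexpr.iloc[:, :1], discovery_run.signatures, n_resample=20)
        res = npb.ntp_classify(
            vexpr.iloc[:, :1], discovery_run.signatures, n_resample=50, seed=7,
            ref_mean=vexpr.mean(axis=1), ref_sd=vexpr.std(axis=1, ddof=0),
        )
        assert len(res) == 1

    def test_sample_order_equivariance(self, discovery_run):
        vexpr, _ = npb.simulate_validation_cohort(discovery_run.study, 30, seed=25)
        r1 = npb.ntp_classify(vexpr, discovery_run.signatures, n_resample=50, seed=8)
        r2 = npb.ntp_classify(
            vexpr[list(vexpr.columns[::-1])], discovery_run.signatures,
            n_resample=50, seed=8,
        )
        assert (r1.loc[r2.index, "predicted"] == r2["predicted"]).all()
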