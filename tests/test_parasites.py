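import numpy as np
import pytest

from marshweb import (ENVIRONMENT, FoodWeb, LifeStage, ParasiteRecord,
                      filter_viable_parasites, host_richness,
                      infer_trophic_links, read_parasite_table,
                      write_parasite_table)


def _web(labels, links):
    A = np.zeros((len(labels), len(labels)), int)
    idx = {l: i for i, l in enumerate(labels)}
    for consumer, resource in links:
        A[idx[consumer], idx[resource]] = 1
    return FoodWeb(tuple(labels), A, name="toy")


@pytest.fixture
def fluke():
    """Two-stage trophic parasite: snail first, bird definitive."""
    return ParasiteRecord("fluke", (LifeStage({"snail"}, "direct"),
                                    LifeStage({"bird"}, "trophic")))


class TestViability:
    def test_supported_transition_is_viable(self, fluke):
        web = _web(["snail", "fish", "bird"], [("bird", "snail")])
        assert [r.name for r in filter_viable_parasites(web, [fluke])] == ["fluke"]

    def test_missing_stage_host_excludes(self, fluke):
        web = _web(["fish", "bird"], [("bird", "fish")])
        with pytest.warns(UserWarning, match="absent"):
            assert filter_viable_parasites(web, [fluke]) == []

    def test_unsupported_trophic_transition_excludes_strictly(self, fluke):
        web = _web(["snail", "bird"], [])  # both present, bird never eats snail
        assert filter_viable_parasites(web, [fluke]) == []
        relaxed = filter_viable_parasites(web, [fluke],
                                          require_trophic_support=False)
        assert [r.name for r in relaxed] == ["fluke"]

    def test_environment_stage_always_present(self):
        rec = ParasiteRecord("mono", (LifeStage({ENVIRONMENT}, "direct"),
                                      LifeStage({"fish"}, "direct")))
        web = _web(["fish"], [])
        assert [r.name for r in filter_viable_parasites(web, [rec])] == ["mono"]

    def test_removing_species_never_rescues_a_parasite(self, fluke):
        full = _web(["snail", "fish", "bird"],
                    [("bird", "snail"), ("fish", "snail"), ("bird", "fish")])
        worm = ParasiteRecord("worm", (LifeStage({"snail"}, "direct"),
                                       LifeStage({"fish"}, "trophic"),
                                       LifeStage({"bird"}, "trophic")))
        records = [fluke, worm]
        viable_full = {r.name for r in filter_viable_parasites(full, records)}
        import warnings
        for drop in full.labels:
            keep = [l for l in full.labels if l != drop]
            idx = [full.index(l) for l in keep]
            sub = FoodWeb(tuple(keep), full.A[np.ix_(idx, idx)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # dropped label reported absent
                viable_sub = {r.name
                              for r in filter_viable_parasites(sub, records)}
            assert viable_sub <= viable_full


class TestLinkInference:
    def test_link_added_for_intermediate_host(self, fluke):
        web = _web(["snail", "bird"], [])
        aug, prov = infer_trophic_links(web, [fluke])
        assert aug.A[aug.index("bird"), aug.index("snail")] == 1
        assert prov.iloc[0]["provenance"] == "parasite-inferred"

    def test_existing_link_unchanged(self, fluke):
        web = _web(["snail", "bird"], [("bird", "snail")])
        aug, prov = infer_trophic_links(web, [fluke])
        assert aug == web and prov.empty

    def test_idempotent(self, fluke):
        web = _web(["snail", "bird"], [])
        once, _ = infer_trophic_links(web, [fluke])
        twice, prov = infer_trophic_links(once, [fluke])
        assert twice == once and prov.empty

    def test_never_removes_links(self, random_web_factory, fluke):
        web = random_web_factory(S=10, fill=0.3, seed=3)
        aug, _ = infer_trophic_links(web, [fluke])
        assert aug.n_links >= web.n_links
        assert np.all(aug.A >= web.A)


class TestRichness:
    def test_double_counting_identity(self):
        web = _web(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])
        records = [
            ParasiteRecord("p1", (LifeStage({"b", "c"}, "direct"),
                                  LifeStage({"a"}, "trophic"))),
            ParasiteRecord("p2", (LifeStage({"c"}, "direct"),)),
        ]
        viable = filter_viable_parasites(web, records)
        inc = host_richness(web, viable)
        total = sum(len([h for h in r.all_hosts() if h in web.labels])
                    for r in viable)
        assert inc["richness"].sum() == total

    def test_unused_host_gets_zero_and_stays(self):
        web = _web(["a", "b"], [("a", "b")])
        rec = ParasiteRecord("p", (LifeStage({"b"}, "direct"),))
        inc = host_richness(web, [rec]).set_index("host")
        assert inc.loc["a", "richness"] == 0
        assert inc.loc["b", "richness"] == 1

    def test_host_at_two_stages_counts_once(self):
        web = _web(["a", "b"], [("a", "b"), ("a", "a")])
        rec = ParasiteRecord("p", (LifeStage({"a"}, "direct"),
                                   LifeStage({"a"}, "trophic")))
        inc = host_richness(web, [rec]).set_index("host")
        assert inc.loc["a", "richness"] == 1

    def test_host_in_all_records(self):
        web = _web(["hub", "x"], [("hub", "x")])
        records = [ParasiteRecord(f"p{i}", (LifeStage({"hub"}, "direct"),))
                   for i in range(25)]
        inc = host_richness(web, records).set_index("host")
        assert inc.loc["hub", "richness"] == 25


class TestTableIO:
    def test_round_trip(self, tmp_path, fluke):
        worm = ParasiteRecord("worm", (LifeStage({"snail", ENVIRONMENT},
                                                 "direct"),
                                       LifeStage({"fish"}, "trophic"),
                                       LifeStage({"bird"}, "trophic")),
                              source="empirical")
        path = tmp_path / "parasites.csv"
        write_parasite_table([fluke, worm], path)
        back = read_parasite_table(path)
        assert {r.name for r in back} == {"fluke", "worm"}
        worm_back = next(r for r in back if r.name == "worm")
        assert worm_back.n_stages == 3
        assert worm_back.stages[0].hosts == frozenset({"snail", ENVIRONMENT})
        assert worm_back.source == "empirical"

    def test_bad_stage_indices_rejected(self, tmp_path):
        path = tmp_path / "parasites.csv"
        path.write_text("parasite,stage_index,transmission,hosts,source\n"
                        "p,1,direct,a,literature\n"
                        "p,3,trophic,b,literature\n")
        with pytest.raises(ValueError, match="stage indices"):
            read_parasite_table(path)
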