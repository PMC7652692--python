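"""Wire-contract tests: the three API calls, round gating, transports."""

import threading

import numpy as np
import pytest

import fedbench as fb
from fedbench.federation import client_seed
from fedbench.models import encode_payload
from fedbench.protocol import (
    FederationServer,
    HttpTransport,
    LoopbackTransport,
    ProtocolError,
    http_server,
    participation_loop,
)


@pytest.fixture(scope="module")
def problem():
    cfg = fb.GeneratorConfig("image10", n_train=150, n_test=40, seed=6)
    train, test = fb.generate_split_pair(cfg)
    spec = fb.ModelSpec("linear_oracle", n_features=784, n_classes=10)
    plan = fb.partition_basic(train, 3, 50, seed=1)
    return train, test, spec, plan


def _shard_data(train, shard):
    return [train.records[i] for i in shard.record_indices], train.labels[shard.record_indices]


def _fresh_server(spec, plan, rounds=3, seed=4):
    return FederationServer(spec, fb.build(spec, seed=seed), plan.client_ids, rounds)


def _trained_payload(spec, server, train, shard, cfg, rnd):
    recs, labs = _shard_data(train, shard)
    w = fb.WeightSet.from_payload(server.get_weight())
    trained = fb.local_train(spec, w, recs, labs, cfg, seed=client_seed(cfg.seed, rnd, shard.client_id))
    return trained.to_payload()


class TestServerCalls:
    def test_initial_round_is_zero(self, problem):
        *_, spec, plan = problem
        assert _fresh_server(spec, plan).get_round() == 0

    def test_get_weight_round_trips_initial_build(self, problem):
        *_, spec, plan = problem
        server = _fresh_server(spec, plan, seed=4)
        w = fb.WeightSet.from_payload(server.get_weight())
        assert w.equal(fb.build(spec, seed=4))

    def test_uninitialized_weights_flagged(self, problem):
        *_, spec, plan = problem
        server = FederationServer(spec, None, plan.client_ids, 1)
        with pytest.raises(ProtocolError, match="uninitialized"):
            server.get_weight()

    def test_round_advances_only_when_all_clients_report(self, problem):
        train, _, spec, plan = problem
        server = _fresh_server(spec, plan)
        cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=3, seed=4)
        for i, shard in enumerate(plan.shards):
            payload = _trained_payload(spec, server, train, shard, cfg, 0)
            res = server.put_weight(shard.client_id, 0, payload, shard.n_k)
            assert res["status"] == "accepted"
            assert server.get_round() == (1 if i == len(plan.shards) - 1 else 0)
        assert server.aggregations == 1

    def test_duplicate_submission_told_to_wait(self, problem):
        train, _, spec, plan = problem
        server = _fresh_server(spec, plan)
        cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=3, seed=4)
        shard = plan.shards[0]
        payload = _trained_payload(spec, server, train, shard, cfg, 0)
        assert server.put_weight(shard.client_id, 0, payload, shard.n_k)["status"] == "accepted"
        again = server.put_weight(shard.client_id, 0, payload, shard.n_k)
        assert again["status"] == "already_participated"
        assert server.aggregations == 0  # no double aggregation

    def test_stale_round_rejected(self, problem):
        *_, spec, plan = problem
        server = _fresh_server(spec, plan)
        payload = server.get_weight()
        assert server.put_weight(plan.shards[0].client_id, 5, payload, 1)["status"] == "stale_round"

    def test_unknown_client_rejected(self, problem):
        *_, spec, plan = problem
        server = _fresh_server(spec, plan)
        res = server.put_weight("intruder", 0, server.get_weight(), 1)
        assert res["status"] == "unknown_client"

    def test_aggregate_matches_engine_fedavg(self, problem):
        """After one full round the served global weights equal the FedAVG
        the engine computes from the same updates."""
        train, _, spec, plan = problem
        server = _fresh_server(spec, plan)
        cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=3, seed=4)
        updates = []
        w0 = fb.WeightSet.from_payload(server.get_weight())
        for shard in plan.shards:
            recs, labs = _shard_data(train, shard)
            trained = fb.local_train(
                spec, w0, recs, labs, cfg, seed=client_seed(cfg.seed, 0, shard.client_id)
            )
            updates.append(fb.federation.ClientUpdate(shard.client_id, 0, trained, shard.n_k))
            server.put_weight(shard.client_id, 0, trained.to_payload(), shard.n_k)
        expect = fb.fedavg(updates)
        got = fb.WeightSet.from_payload(server.get_weight())
        assert got.equal(expect)


def _run_clients(server, transports, plan, train, spec, cfg):
    results = {}
    threads = []
    for shard, transport in zip(plan.shards, transports):
        recs, labs = _shard_data(train, shard)

        def worker(s=shard, t=transport, r=recs, l=labs):
            results[s.client_id] = participation_loop(t, s.client_id, r, l, spec, cfg)

        th = threading.Thread(target=worker)
        threads.append(th)
        th.start()
    for th in threads:
        th.join(timeout=120)
    return results


def test_loopback_three_clients_five_rounds_fifteen_puts(problem):
    train, _, spec, plan = problem
    server = _fresh_server(spec, plan, rounds=5)
    cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=5, seed=4)
    transports = [LoopbackTransport(server) for _ in plan.shards]
    results = _run_clients(server, transports, plan, train, spec, cfg)
    assert sum(len(v) for v in results.values()) == 15
    assert all(v == [0, 1, 2, 3, 4] for v in results.values())
    assert server.get_round() == 5


def test_http_and_loopback_runs_are_bit_identical(problem):
    train, _, spec, plan = problem
    cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=3, seed=4)

    loop_server = _fresh_server(spec, plan)
    _run_clients(loop_server, [LoopbackTransport(loop_server) for _ in plan.shards],
                 plan, train, spec, cfg)

    http_srv = _fresh_server(spec, plan)
    with http_server(http_srv) as url:
        _run_clients(http_srv, [HttpTransport(url) for _ in plan.shards],
                     plan, train, spec, cfg)

    assert loop_server.global_weights.equal(http_srv.global_weights)
    assert encode_payload(loop_server.global_weights.to_payload()) == encode_payload(
        http_srv.global_weights.to_payload()
    )


def test_protocol_run_matches_engine_run(problem):
    """Simulated (run_experiment) and protocol-driven federations agree
    bit-for-bit given the same seeds."""
    train, test, spec, plan = problem
    cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=3, seed=4)
    res = fb.run_experiment(train, test, plan, spec, cfg)
    server = _fresh_server(spec, plan, seed=cfg.seed)
    _run_clients(server, [LoopbackTransport(server) for _ in plan.shards],
                 plan, train, spec, cfg)
    assert server.global_weights.equal(res.final_weights)


def test_http_round_and_weight_endpoints(problem):
    *_, spec, plan = problem
    server = _fresh_server(spec, plan, seed=7)
    with http_server(server) as url:
        t = HttpTransport(url)
        assert t.get_round() == 0
        w = fb.WeightSet.from_payload(t.get_weight())
        assert w.equal(fb.build(spec, seed=7))
        res = t.put_weight(plan.shards[0].client_id, 9, w.to_payload(), 5)
        assert res["status"] == "stale_round"


def test_finished_server_tells_clients_to_stop(problem):
    train, _, spec, plan = problem
    server = _fresh_server(spec, plan, rounds=0)
    cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=0, seed=4)
    rounds = participation_loop(
        LoopbackTransport(server), plan.shards[0].client_id,
        *_shard_data(train, plan.shards[0]), spec, cfg,
    )
    assert rounds == []


def test_fractional_participation_threshold(problem):
    """With the aggregation threshold lowered, a round can close before the
    whole roster reports (ablation mode; the default requires everyone)."""
    train, _, spec, plan = problem
    server = FederationServer(
        spec, fb.build(spec, seed=4), plan.client_ids, 3, participation_threshold=0.5
    )
    cfg = fb.TrainingConfig(local_epochs=1, batch_size=25, max_rounds=3, seed=4)
    for shard in plan.shards[:2]:  # 2 of 3 >= ceil(0.5 * 3)
        payload = _trained_payload(spec, server, train, shard, cfg, 0)
        server.put_weight(shard.client_id, 0, payload, shard.n_k)
    assert server.get_round() == 1
    assert server.aggregations == 1
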