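"""Policies: random, Optimum, MAB, SARSA, DQN, grid search."""

import collections

import numpy as np
import pytest
from scipy import stats

from menurec.catalog import Dish, MenuDay, sample_daily_menu
from menurec.env import HistoryState, Transition, advance_state, compute_reward, simulate_selection
from menurec.policies import (
    DQNConfig,
    DQNPolicy,
    MABPolicy,
    OptimumPolicy,
    PolicyConfig,
    RandomPolicy,
    SarsaPolicy,
    grid_search,
    sarsa_update,
)
from menurec.policies.dqn import StoredTransition, encode_action, encode_window
from menurec.policies.nets import Adam, LSTMQNetwork
from menurec.profiles import UserAttributes, UserProfile
from menurec.tags import COURSES, TAGS


def _profile(tastes, diet="omnivore", innovation=0.5, user_id="u"):
    full = {t: 0.0 for t in TAGS}
    full.update(tastes)
    return UserProfile(user_id, diet, full, innovation, UserAttributes(30, "female", "coastal", "large"))


def _menu(first_tags=("pasta", "rice", "vegetables"), second_tags=("egg", "legume", "potato"),
          dessert_tags=("fruit", "dairy")):
    def dishes(course, tags):
        return tuple(
            Dish(f"{course}-{t}", t, course, t,
                 vegetarian=t not in ("white_meat", "red_meat", "fish"),
                 vegan=t not in ("white_meat", "red_meat", "fish", "egg", "dairy"))
            for t in tags
        )

    return MenuDay(day=0, options={
        "first": dishes("first", first_tags),
        "second": dishes("second", second_tags),
        "dessert": dishes("dessert", dessert_tags),
    })


def _state(user_id="u"):
    return HistoryState(user_id=user_id, w=3)


def _transition(state, menu, recommended, selected_idx):
    selected = {c: menu.options[c][selected_idx.get(c, 0)] for c in COURSES}
    reward = compute_reward(recommended, selected)
    return Transition(state, recommended, {c: d.tag for c, d in selected.items()},
                      reward, advance_state(state, selected))


class TestRandomPolicy:
    def test_single_tag_course_returns_that_tag(self, rng):
        # three distinct dishes sharing one tag: the recommendation is forced
        base = _menu()
        menu = MenuDay(day=0, options={
            "first": tuple(Dish(f"f{i}", "pasta", "first", "pasta", vegetarian=True, vegan=True) for i in range(3)),
            "second": base.options["second"],
            "dessert": base.options["dessert"],
        })
        assert RandomPolicy().recommend("u", _state(), menu, rng)["first"] == "pasta"

    def test_recommendations_uniform_over_options(self):
        rng = np.random.default_rng(0)
        menu = _menu()
        policy = RandomPolicy()
        counts = collections.Counter(policy.recommend("u", _state(), menu, rng)["first"] for _ in range(30_000))
        p = stats.chisquare(list(counts.values())).pvalue
        assert set(counts) == {"pasta", "rice", "vegetables"}
        assert p > 0.01


class TestOptimumPolicy:
    def test_recommends_argmax_taste(self, rng):
        profile = _profile({"pasta": 0.9, "rice": 0.05, "vegetables": 0.05, "egg": 1.0, "fruit": 1.0})
        policy = OptimumPolicy({"u": profile})
        assert policy.recommend("u", _state(), _menu(), rng)["first"] == "pasta"

    def test_best_available_when_favorite_absent(self, rng):
        profile = _profile({"fish": 1.0, "legume": 0.4, "egg": 0.2, "potato": 0.1, "fruit": 1.0,
                            "pasta": 0.3, "rice": 0.2, "vegetables": 0.1})
        policy = OptimumPolicy({"u": profile})
        # fish not offered among seconds here
        assert policy.recommend("u", _state(), _menu(), rng)["second"] == "legume"

    def test_ties_break_alphabetically(self, rng):
        profile = _profile({"pasta": 0.5, "rice": 0.5, "vegetables": 0.1, "egg": 1.0, "fruit": 1.0})
        policy = OptimumPolicy({"u": profile})
        assert policy.recommend("u", _state(), _menu(), rng)["first"] == "pasta"

    def test_optimum_dominates_other_policies(self, catalog):
        # dominance simulation: 5 users x 100 days, shared selections
        rng = np.random.default_rng(5)
        profiles = {}
        for i in range(5):
            tastes = {t: float(rng.random()) for t in TAGS}
            profiles[f"u{i}"] = _profile(tastes, user_id=f"u{i}")
        policies = {
            "optimum": OptimumPolicy(profiles),
            "random": RandomPolicy(),
            "mab": MABPolicy(PolicyConfig()),
        }
        totals = {name: 0 for name in policies}
        states = {(n, u): _state(u) for n in policies for u in profiles}
        for day in range(100):
            for uid, profile in profiles.items():
                menu = sample_daily_menu(catalog, rng, day)
                selection = simulate_selection(profile, menu, rng)
                for name, policy in policies.items():
                    rec = policy.recommend(uid, states[(name, uid)], menu, rng)
                    reward = compute_reward(rec, selection)
                    totals[name] += sum(reward.values())
                    nxt = advance_state(states[(name, uid)], selection)
                    policy.observe(uid, Transition(states[(name, uid)], rec,
                                                   {c: d.tag for c, d in selection.items()}, reward, nxt))
                    states[(name, uid)] = nxt
        assert totals["optimum"] >= totals["mab"] >= 0
        assert totals["optimum"] >= totals["random"]


class TestMAB:
    def test_full_exploration_matches_random_distribution(self):
        rng = np.random.default_rng(1)
        policy = MABPolicy(PolicyConfig(epsilon=1.0))
        menu = _menu()
        counts = collections.Counter(policy.recommend("u", _state(), menu, rng)["first"] for _ in range(10_000))
        assert stats.chisquare(list(counts.values())).pvalue > 0.01

    def test_greedy_converges_to_constant_preference(self):
        # epsilon = 0; user always selects pasta; full-information update
        rng = np.random.default_rng(2)
        policy = MABPolicy(PolicyConfig(epsilon=0.0), update_rule="selection")
        menu = _menu()
        state = _state()
        for _ in range(30):
            rec = policy.recommend("u", state, menu, rng)
            tr = _transition(state, menu, rec, {"first": 0})  # pasta is option 0
            policy.observe("u", tr)
            state = tr.next_state
        assert policy.recommend("u", state, menu, rng)["first"] == "pasta"

    def test_selection_rule_propensity_is_empirical_frequency(self):
        rng = np.random.default_rng(3)
        policy = MABPolicy(PolicyConfig(epsilon=0.5), update_rule="selection")
        menu = _menu()
        state = _state()
        for i in range(10):
            rec = policy.recommend("u", state, menu, rng)
            tr = _transition(state, menu, rec, {"first": 0 if i < 7 else 1})
            policy.observe("u", tr)
            state = tr.next_state
        mab = policy.states["u"]
        assert mab.propensity("first", "pasta", "selection") == pytest.approx(0.7)
        assert mab.propensity("first", "rice", "selection") == pytest.approx(0.3)

    def test_match_rule_tracks_match_rate_of_recommended_arm(self):
        rng = np.random.default_rng(4)
        policy = MABPolicy(PolicyConfig(epsilon=0.0), update_rule="match")
        menu = _menu()
        state = _state()
        for _ in range(40):
            rec = policy.recommend("u", state, menu, rng)
            tr = _transition(state, menu, rec, {"first": 0})
            policy.observe("u", tr)
            state = tr.next_state
        # the pasta arm, once found, is a guaranteed match and stays greedy
        assert policy.recommend("u", state, menu, rng)["first"] == "pasta"
        assert policy.states["u"].propensity("first", "pasta", "match") == 1.0


class TestSarsa:
    def test_update_arithmetic(self):
        q = {}
        sarsa_update(q, "s", "a", 1.0, "s2", "a2", alpha=0.5, gamma=0.0)
        assert q[("s", "a")] == pytest.approx(0.5)
        sarsa_update(q, "s", "a", 1.0, "s2", "a2", alpha=0.5, gamma=0.0)
        assert q[("s", "a")] == pytest.approx(0.75)

    def test_zero_reward_is_fixed_point(self):
        q = {}
        for _ in range(10):
            sarsa_update(q, "s", "a", 0.0, "s", "a", alpha=0.5, gamma=0.9)
        assert q[("s", "a")] == 0.0

    def test_bellman_fixed_point_on_self_loop(self):
        # constant r=1 on one (s, a) loop: Q -> 1 / (1 - gamma) = 10
        q = {}
        for _ in range(3000):
            sarsa_update(q, "s", "a", 1.0, "s", "a", alpha=0.1, gamma=0.9)
        assert q[("s", "a")] == pytest.approx(10.0, abs=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sarsa_update({}, "s", "a", 1.0, "s", "a", alpha=0.0, gamma=0.9)
        with pytest.raises(ValueError):
            sarsa_update({}, "s", "a", 1.0, "s", "a", alpha=0.1, gamma=1.5)

    def test_policy_learns_constant_preference(self):
        rng = np.random.default_rng(6)
        policy = SarsaPolicy(PolicyConfig(epsilon=0.1, sarsa_alpha=0.5, gamma=0.5))
        menu = _menu()
        state = _state()
        for _ in range(200):
            rec = policy.recommend("u", state, menu, rng)
            tr = _transition(state, menu, rec, {"first": 0})
            policy.observe("u", tr)
            state = tr.next_state
        q = policy.tables["u"]["first"]
        assert q[("pasta", "pasta")] == max(q.get(("pasta", t), 0.0) for t in ("pasta", "rice", "vegetables"))


class TestNetwork:
    def test_gradients_match_finite_differences(self):
        net = LSTMQNetwork(4, 3, lstm_units=5, hidden_units=4, rng=np.random.default_rng(0))
        rng = np.random.default_rng(1)
        S = rng.random((6, 3, 4))
        A = rng.random((6, 3))
        Y = rng.random(6)
        _, grads = net.mse_gradients(S, A, Y)
        eps = 1e-6
        for key in net.params:
            flat = net.params[key].ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                up, _ = net.mse_gradients(S, A, Y)
                flat[idx] = orig - eps
                down, _ = net.mse_gradients(S, A, Y)
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), key

    def test_adam_reduces_loss(self):
        net = LSTMQNetwork(4, 3, lstm_units=5, hidden_units=4, rng=np.random.default_rng(0))
        opt = Adam(net.params, lr=1e-2)
        rng = np.random.default_rng(1)
        S, A, Y = rng.random((16, 3, 4)), rng.random((16, 3)), rng.random(16)
        first, _ = net.mse_gradients(S, A, Y)
        for _ in range(200):
            _, grads = net.mse_gradients(S, A, Y)
            opt.step(net.params, grads)
        last, _ = net.mse_gradients(S, A, Y)
        assert last < first / 2


class TestDQN:
    def _policy(self, **overrides):
        config = DQNConfig(**overrides)
        return DQNPolicy(config, rng=np.random.default_rng(0))

    def test_full_exploration_matches_random_distribution(self):
        rng = np.random.default_rng(1)
        policy = self._policy(epsilon=1.0, epsilon_floor=1.0)
        menu = _menu()
        counts = collections.Counter(policy.recommend("u", _state(), menu, rng)["first"] for _ in range(10_000))
        assert stats.chisquare(list(counts.values())).pvalue > 0.01

    def test_target_sync_copies_q_outputs(self):
        policy = self._policy()
        rng = np.random.default_rng(2)
        policy.net.params["W1"] += rng.normal(0, 0.1, policy.net.params["W1"].shape)
        policy.target_net.sync_from(policy.net)
        for _ in range(100):
            s = rng.random((policy.config.window_days, 36))
            encs = [encode_action("first", t) for t in ("pasta", "rice")]
            assert np.allclose(policy.q_values(s, encs), policy.q_values(s, encs, policy.target_net))

    def test_batched_q_matches_one_at_a_time_oracle(self):
        policy = self._policy()
        rng = np.random.default_rng(3)
        s = rng.random((policy.config.window_days, 36))
        tags = ("pasta", "rice", "vegetables")
        encs = [encode_action("first", t) for t in tags]
        batched = policy.q_values(s, encs)
        single = [policy.q_values(s, [e])[0] for e in encs]
        assert np.allclose(batched, single)

    def test_gamma_zero_targets_reduce_to_rewards(self):
        # hand-computed loss on a 3-transition memory
        policy = self._policy(gamma=0.0, replay_sample_size=3, batch_size=3,
                              epochs_per_training=1, burn_in_day=0, dropout_rate=0.0)
        rng = np.random.default_rng(4)
        rewards = [1.0, 0.0, 1.0]
        items = []
        for r in rewards:
            s = rng.random((3, 36))
            items.append(StoredTransition(s, encode_action("first", "pasta"), r, s, (encode_action("first", "rice"),)))
            policy.memory.push(items[-1])
        S = np.stack([t.state for t in items])
        A = np.stack([t.action for t in items])
        q = policy.net.forward(S, A)
        expected_loss = 0.5 * np.mean((q - np.asarray(rewards)) ** 2)
        loss, _ = policy.net.mse_gradients(S, A, np.asarray(rewards))
        assert loss == pytest.approx(expected_loss)

    def test_epsilon_decays_per_training(self):
        policy = self._policy(replay_sample_size=2, batch_size=2, epochs_per_training=1,
                              burn_in_day=0)
        rng = np.random.default_rng(5)
        s = rng.random((3, 36))
        for r in (1.0, 0.0):
            policy.memory.push(StoredTransition(s, encode_action("first", "pasta"), r, s,
                                                (encode_action("first", "rice"),)))
        for _ in range(5):
            assert policy.train_step(rng)
        assert policy.epsilon == pytest.approx(0.15 - 5 * 0.01)

    def test_training_skipped_without_enough_memory(self):
        policy = self._policy(replay_sample_size=10, burn_in_day=0)
        assert not policy.train_step(np.random.default_rng(0))

    def test_degenerate_user_converges(self, catalog):
        # always-pasta user: favorite tag recommended on >= 80% of the last
        # 50 days on which it is offered
        rng = np.random.default_rng(10)
        policy = self._policy()
        tastes = {t: 0.0 for t in TAGS}
        tastes.update({"pasta": 1.0, "fruit": 1.0, "egg": 1.0})
        state = _state()
        offered_hits = []
        for day in range(200):
            menu = sample_daily_menu(catalog, rng, day)
            rec = policy.recommend("u", state, menu, rng)
            selected = {}
            for c in COURSES:
                best = max(menu.options[c], key=lambda d: tastes[d.tag])
                for d in menu.options[c]:
                    if d.tag == "pasta":
                        best = d
                selected[c] = best
            reward = compute_reward(rec, selected)
            nxt = advance_state(state, selected)
            policy.observe("u", Transition(state, rec, {c: d.tag for c, d in selected.items()}, reward, nxt))
            state = nxt
            if "pasta" in menu.tags("first"):
                offered_hits.append(rec["first"] == "pasta")
        assert np.mean(offered_hits[-50:]) >= 0.8

    def test_window_encoding_pads_missing_days_with_zeros(self):
        enc = encode_window((("pasta", "egg", "fruit"),), 3)
        assert enc.shape == (3, 36)
        assert np.all(enc[:2] == 0.0)
        assert enc[2].sum() == 3.0


class TestGridSearch:
    def test_single_point_space_returns_it(self, rng):
        best, results = grid_search({"epsilon": [0.2]}, lambda cfg, r: 1.0, repetitions=2, rng=rng)
        assert best == {"epsilon": 0.2}
        assert len(results) == 1

    def test_exploitation_dominates_on_strong_preferences(self, catalog):
        # two-point space: epsilon 1.0 vs 0.05 on an always-pasta user; the
        # exploiting configuration must win
        profile = _profile({"pasta": 1.0, "fruit": 1.0, "egg": 1.0})

        def evaluate(cfg, rng):
            policy = MABPolicy(PolicyConfig(epsilon=cfg["epsilon"]), update_rule="selection")
            state = _state()
            total = 0
            for day in range(60):
                menu = sample_daily_menu(catalog, rng, day)
                rec = policy.recommend("u", state, menu, rng)
                sel = simulate_selection(profile, menu, rng)
                reward = compute_reward(rec, sel)
                total += sum(reward.values())
                nxt = advance_state(state, sel)
                policy.observe("u", Transition(state, rec, {c: d.tag for c, d in sel.items()}, reward, nxt))
                state = nxt
            return float(total)

        best, _ = grid_search({"epsilon": [1.0, 0.05]}, evaluate, repetitions=3,
                              rng=np.random.default_rng(8))
        assert best == {"epsilon": 0.05}

    def test_empty_space_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search({}, lambda cfg, r: 0.0, rng=rng)
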