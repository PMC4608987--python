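"""Derive sickness-absence aggregates from a raw episode register.

Shows the register conventions: episodes separated by fewer than 28 calendar
days merge into one episode, day counts are inclusive of both endpoints, and
the gap days between merged constituents are worked days that do not count.
"""

import datetime as dt

from riskreclass import Episode, EpisodeRegister, aggregate_register, merge_episodes

d = lambda k: dt.date(2007, 1, 1) + dt.timedelta(days=k - 1)  # noqa: E731

episodes = (
    Episode(d(1), d(10), "worker_a"),    # 10 days
    Episode(d(30), d(35), "worker_a"),   # 6 days, gap of 19 -> merges
    Episode(d(200), d(201), "worker_a"), # separate episode
    Episode(d(1), d(10), "worker_b"),
    Episode(d(39), d(40), "worker_b"),   # gap of exactly 28 -> stays separate
)
register = EpisodeRegister(episodes, (d(1), d(365)))

for worker in ("worker_a", "worker_b"):
    eps = [e for e in episodes if e.worker_id == worker]
    merged = merge_episodes(eps, min_gap_days=28)
    print(f"{worker}: {len(eps)} recorded episodes -> {len(merged)} after merging")

print()
for worker, (days, n_eps) in sorted(aggregate_register(register, 28).items()):
    print(f"{worker}: {days} SA days, {n_eps} SA episodes "
          f"(high SA days: {days >= 30}, high SA episodes: {n_eps >= 3})")
print()
print("worker_a's first two episodes merge (gap 19 < 28) but contribute only")
print("their own 10+6 days; worker_b's 28-day gap keeps two episodes.")
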