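# Small demo corpus spec for `cigartopics synth`.
# Plants four topics with a Flavors/Swisher-use coupling and light
# contamination; recovery should be exact per tweet.
n_tweets: 2000
topic_probs:
  Person tagging: 0.33
  Flavors: 0.21
  Swisher use: 0.17
  Cannabis use: 0.06
pairwise_boost:
  "Flavors|Swisher use": 0.10
noise_prob: 0.0
retweet_frac: 0.15
non_english_frac: 0.06
bot_frac: 0.04
surname_frac: 0.02
n_authors: 1500
seed: 2018
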