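# Location-category dictionary for vaping-related post classification.
# 11 categories; keywords are matched as whole lemmatized tokens
# (multi-word entries as contiguous lemmatized phrases).

[Social venues]
game
party
park
beach
concert

[Living space]
home
bedroom
hotel
house
apartment

[Stores]
shop
store
market
gym
mall

[Modes of transportation]
car
drive
train
bus
airplane

[School]
school
class
college
classroom
campus

[Workplace]
work
job
workplace
office

[Healthcare offices]
doctor
dentist
drugstore
hospital
pharmacy

[Eateries]
restaurant
café
cafe
boba
diner

[Correctional facility]
court
prison
jail

[Religious institutions]
church
chapel
temple
mosque

[Miscellaneous]
place
town
downtown
neighborhood
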