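about
above
after
again
almost
along
always
amber
anchor
answer
around
arrow
autumn
banner
basket
because
before
below
between
border
bottle
breeze
bridge
bright
button
camera
candle
canyon
carpet
castle
cellar
circle
cloud
coffee
copper
corner
cotton
curtain
desert
drawer
during
early
either
engine
evening
fabric
feather
fiction
finger
flavor
follow
forest
fountain
garden
gather
glacier
granite
guitar
hammer
harbor
hollow
island
jacket
journey
kettle
ladder
lantern
laughter
letter
little
lumber
machine
mantle
marble
meadow
mirror
morning
mountain
narrow
needle
number
orange
orchard
other
painter
paper
pebble
pencil
picture
pillow
planet
pocket
puzzle
quarry
rather
ribbon
river
saddle
sailor
seldom
shadow
shelter
silver
simple
socket
spring
street
string
summer
sunset
table
thunder
timber
together
tunnel
under
valley
velvet
village
violet
wagon
walnut
window
winter
wonder
yellow
yonder
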