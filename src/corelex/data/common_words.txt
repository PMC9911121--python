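# Known-lemma dictionary for the fallback analyzer's suffix rules, and the
# source pool for the synthetic generator's distractor vocabulary (filtered
# per task so no distractor can credit a checklist item).  One word per line.
a
about
after
again
all
also
always
and
animal
any
apple
ask
at
baby
back
ball
banana
bark
basket
be
beautiful
because
become
bedroom
begin
believe
big
bird
blanket
blue
boat
book
bottle
bowl
box
boy
branch
bread
break
breakfast
bridge
bring
brother
brush
build
bus
but
butter
button
buy
by
call
camera
can
candle
car
carpet
carriage
castle
cat
catch
chair
change
child
choose
cinderella
circus
city
climb
clock
cloud
clown
coffee
comb
come
computer
cook
corner
cotton
country
cup
dad
daddy
dance
daughter
day
department
dinner
do
doctor
dog
door
down
draw
dream
dress
drive
eat
elephant
engine
evening
fairy
fall
farm
father
feel
find
fire
fireman
first
fish
fit
flood
floor
flower
fly
foot
for
forest
forget
fork
friend
from
garden
gas
get
gift
girl
give
glass
go
godmother
good
goose
grass
green
guitar
hair
hand
happen
happy
hat
have
he
hear
hello
help
her
here
him
his
hold
home
horse
hospital
house
i
in
into
island
it
jacket
jelly
jump
just
keep
kick
kind
kitchen
kite
knife
knock
know
ladder
lamp
leaf
learn
leave
lemon
let
letter
like
lion
little
live
look
lose
lot
love
magic
make
mama
man
market
marry
may
maybe
me
mean
meet
midnight
mirror
mom
mommy
monkey
more
morning
most
mother
mountain
mouse
move
music
my
need
never
new
news
night
no
not
now
number
ocean
of
off
okay
old
on
one
only
open
orange
other
ought
out
over
pa
paint
palace
pants
papa
paper
parade
park
pay
peanut
pencil
person
phone
picture
piece
pillow
pink
place
plane
planet
plant
plate
play
please
pocket
policeman
prince
pumpkin
purple
put
question
quickly
rabbit
radio
rain
read
really
red
ride
ring
rise
river
rocket
room
run
sandwich
say
school
sea
see
send
shall
she
shoe
show
silver
sing
sister
sit
sky
sleep
slice
slipper
slowly
small
so
soap
soccer
some
sort
speak
spend
spider
spoon
spread
stand
star
steal
stepmother
stepsister
stick
stone
stop
story
street
strike
stuck
summer
sun
sweater
swim
table
take
talk
teach
teacher
tell
thank
that
the
them
then
there
these
they
think
this
those
through
throw
ticket
tiger
time
to
today
together
tooth
towel
town
train
tree
truck
try
turn
turtle
two
umbrella
under
understand
up
us
use
very
village
wagon
walk
want
watch
water
we
wear
wet
wheel
when
where
white
who
why
wife
will
win
window
winter
wish
with
woman
word
work
world
write
yellow
yes
you
young
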